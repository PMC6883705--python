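"""Count chromosome fusions and fissions from a painted karyotype.

Paints each simulated chromosome by the ancestral chromosome ("color") and
WGD copy of its genes, then counts the minimum number of fusions and
fissions consistent with the painting.  The arithmetic identity
fusions = initial_units - n_chromosomes + fissions always holds.
"""

from wgdkit.karyotype import count_events, event_arithmetic, paint_from_origins
from wgdkit.simulate import SimulationConfig, generate_scenario

# reduction of a 13-unit karyotype to 7 chromosomes, as in the basal
# eudicot: 7 fusions and a single fission
print("arithmetic check: 13 units -> 7 chromosomes with 1 fission needs",
      event_arithmetic(13, 7, 1), "fusions")
print("post-hexaploidy core genome: 20 -> 19 with 1 fission needs",
      event_arithmetic(20, 19, 1), "fusions (3 rearrangements in total)")

sim = generate_scenario(SimulationConfig(genes_per_chrom=120, inversions_per_lineage=0, seed=5))
for lineage in ("columbine", "grape"):
    painting = paint_from_origins(sim.genomes[lineage], min_run=1)
    units = {(g.color, g.copy_label) for g in sim.genomes[lineage].genes()}
    n_ancestral = sum(
        1 for ev in sim.ledger.events
        if ev["op"] == "fuse" and ev.get("kind") == "ancestral"
    )
    ec = count_events(painting, initial_units=len(units) - n_ancestral)
    logged = sim.ledger.event_counts(lineage)
    print(f"{lineage}: {painting.n_chromosomes} chromosomes; inferred "
          f"{ec.fusions_total} fusions ({ec.fusions_between_paralogs} between WGD paralogs) "
          f"+ {ec.fissions} fissions; ledger logged {logged['fusions']} fusions, "
          f"{logged['fissions']} fissions")
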