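"""Classify the polyploid history of a simulated genome pair.

Combines the partner-ratio summary with per-triplet exclusive-pairing
tests: a 6:3 ratio calls an extra basal WGD (scenario 1); a 2:3 ratio with
confident exclusive pairing calls a shared tetraploidy (scenario 3), and
the leftover chromosome of each triplet separates allohexaploidy (a true
outlier) from autohexaploidy (a duplicated partner); a 2:3 ratio without
pairing support calls independent events (scenario 2).
"""

from wgdkit.simulate import SimulationConfig, generate_scenario
from wgdkit.experiments import classify_simulation, evaluate_call

for scenario, mode in [(3, "allo"), (3, "auto"), (2, "allo"), (1, "allo")]:
    cfg = SimulationConfig(
        scenario=scenario, hexaploidy_mode=mode, genes_per_chrom=120, seed=42
    )
    sim = generate_scenario(cfg)
    call = classify_simulation(sim, N=8, n_perm=50, seed=42, max_colors=5)
    score = evaluate_call(sim, call)
    print(
        f"truth: scenario {scenario} ({mode:4s}) -> call: tetraploidy={call.tetraploidy:22s}"
        f" hexaploidy={call.hexaploidy_mode:12s} correct={score['correct']}"
    )
    if call.outlier_chroms:
        print(f"    outlier (hybrid-derived) chromosomes: {call.outlier_chroms}")
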