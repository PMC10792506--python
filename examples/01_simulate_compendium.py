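"""Generate a synthetic drought compendium with planted regulators.

Builds a bipartite TF -> cell-wall-gene network in which six planted drought
TFs each regulate 30 targets, simulates five control-vs-stress expression
experiments, and writes everything as TSV fixtures.
"""

from pathlib import Path

from drynet import SimulationParams, simulate, write_fixtures

params = SimulationParams(seed=1)  # 60 TFs (6 planted), 800 CWP genes, 5 experiments
net, experiments, truth = simulate(params)
manifest = write_fixtures(Path("scratch/example_fixtures"), net, truth, experiments)

print(f"network: {len(net.tfs)} TFs, {len(net.cwps)} CWP genes, {net.n_edges} edges")
print(f"planted drought TFs: {sorted(truth.planted_tfs)}")
n_true = sum(
    1 for degs in truth.true_deg_sets.values() for d in degs.values() if d != 0
)
print(f"{len(experiments)} experiments, {n_true} true DEG events planted in total")
print(f"fixtures written: {len(manifest['expression'])} expression matrices")
# The planted TFs are the ground truth that the prioritisation pipeline
# (examples 02-04) should rediscover from the expression data alone.
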