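"""Learn feature weights by GA against disease benchmarks with LOOCV.

Uses a reduced schedule (population 12, 8 generations) on a 4-disease
synthetic panel so the example runs in seconds; the default schedule is
100 generations x 120 individuals.
"""

import tempfile
from pathlib import Path

import varprio.ga as ga
from varprio import SimulationSpec, simulate_all
from varprio.pipeline import AnnotationStore

with tempfile.TemporaryDirectory() as tmp:
    spec = SimulationSpec(n_diseases=4, snps_per_gene=30, seed=11)
    simulate_all(spec, tmp)
    store = AnnotationStore.load(Path(tmp) / "store")
    benches = [ga.DiseaseBenchmark.from_yaml(p)
               for p in sorted((Path(tmp) / "benchmarks").glob("*.yaml"))]
    prepared = [ga.prepare_benchmark(b, store.matrix, store.registry)
                for b in benches]

    cfg = ga.GaConfig.scaled(population=12, generations=8, seed=3)
    report = ga.loocv_grid(prepared, epsilon_grid=(0.3, 0.6),
                           tr_grid=(0.25, 0.75), config=cfg)
    print(f"LOOCV: {report.n_runs} runs "
          f"({len(prepared)} diseases x 2 epsilon x 2 Tr)\n")
    print(report.cells.to_string(index=False))

    best, traj = ga.run_ga(prepared, cfg)
    names = store.registry.names
    top = sorted(zip(best.w, names), reverse=True)[:6]
    print(f"\nfinal fit on all diseases: best fitness {best.fitness:.3f} "
          f"after {len(traj)} generations")
    print("highest learned weights:")
    for w, name in top:
        print(f"  {name:<12} {w:.3f}")

print("""
Each LOOCV cell holds one disease out, trains on the rest, and reports the
mean held-out sensitivity/specificity/accuracy.  Fitness below 1 means the
|Y|/|S| < Tr filtering constraint was met; values above 2 carry the graded
infeasibility penalty.  With this demonstration-sized schedule the weight
ranking is still noisy; at the scale of the recovery experiment (30+
generations, population 40) the planted inf_* features reliably out-weigh
the noise features.
""")
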