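"""Compare the fixed-step and variable-step fruit fly optimizers.

Runs both variants on the Drop-Wave and Matyas test functions (10
seeded runs each at a reduced budget) and prints best/mean/std.  The
variable-step schedule scatters early candidates across many orders of
magnitude, which is why it reaches the exact optimum of origin-centred
functions while the fixed step crawls.
"""

from vfoabeta import FOAConfig, benchmark_objective, run_foa, summarize_runs
from vfoabeta.benchmarks import get_spec

for fid in ("F2", "F6"):
    objective = benchmark_objective(fid)
    print(f"\n{fid} ({get_spec(fid).name}):")
    for variant in ("FOA", "VFOA"):
        finals = []
        for r in range(10):
            config = FOAConfig(
                dimension=objective.dimension,
                variant=variant,
                population=50,
                max_iterations=200,
                weight_factor=0.8,
                seed=r,
            )
            finals.append(run_foa(objective, config, batch=True).final_best_value)
        s = summarize_runs(finals)
        print(f"  {variant:4s}  best={s.best:.3g}  mean={s.mean:.3g}  std={s.std:.3g}")

print(
    "\nSmaller is better (both functions are minimized; Drop-Wave's optimum"
    "\nis -1, Matyas's is 0).  VFOA should hit -1 exactly on F2 and reach"
    "\n~1e-45 on F6, orders of magnitude below the fixed-step FOA."
)
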