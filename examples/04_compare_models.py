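"""Personalized vs pooled monitoring models on one parameter sub-grid.

The personalized model (one network per patient) is compared against the
two pooled baselines: a per-patient prefix pool (GMM1) and a cohort-wide
class-stratified random pool (GMM2).  Average accuracy is the unweighted
mean over patients.
"""

from ecgmotif import CohortSpec, SweepGrid, make_cohort, prepare_cohort_beats, run_sweep

beats = prepare_cohort_beats(make_cohort(CohortSpec(seed=42)))
grid = SweepGrid(r_values=(0.8, 1.2), k_values=(2, 6), t_values=(0.1, 0.25))
results = run_sweep(beats, grid)

avg = results[results.patient_id == "AVERAGE"]
table = avg.pivot_table(index=["r", "k", "t"], columns="policy", values="accuracy")
print(table.round(3).to_string())
ops = avg.groupby("policy")["train_ops"].mean()
print("\nmean training distance evaluations per cell:")
print(ops.round(0).to_string())
print("\nEach row is one (R, K, T) cell; the personalized column should never")
print("fall below the pooled ones on this heterogeneous cohort, and its")
print("training cost is an order of magnitude smaller.")
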