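"""End-to-end run: simulate a cohort, train with individual-grouped CV,
and check the FDA-style agreement of held-out predictions.

Grouped cross-validation keeps every patient's windows on one side of
each fold, so all reported numbers describe patients the model never
saw during training — the honest setting for a calibration-free device.
"""

from neobp import PipelineConfig, SimulationConfig, fda_check
from neobp.pipeline import run_end_to_end

cfg = PipelineConfig(n_patients=12, cv_folds=6,
                     simulation=SimulationConfig(duration_s=240.0),
                     sim_seed=42, fold_seed=7, train_seed=7,
                     log_level="WARNING")
result = run_end_to_end(cfg)

c = result.manifest.counts
print(f"patients {c['patients']}, candidate windows {c['candidate_windows']}, "
      f"paired {c['paired_windows']}, held-out predictions {c['evaluated_points']}")

print("\nper-individual-averaged agreement (each patient weighted equally):")
for name, comp in result.report_per_individual.components.items():
    print(f"  {name.upper()}: bias {comp.mae:+5.2f} mmHg, SD {comp.sd:5.2f} mmHg, "
          f"limits of agreement [{comp.loa_low:+.1f}, {comp.loa_high:+.1f}]")

verdict = fda_check(result.report_per_individual)
print("\nFDA accuracy gate (|bias| <= 5 and SD <= 8 mmHg):", verdict)
print("\npooled (every window counted once):")
for name, comp in result.report_pooled.components.items():
    print(f"  {name.upper()}: bias {comp.mae:+5.2f}, SD {comp.sd:5.2f} mmHg")
print("\nPooled SDs run higher than per-individual SDs because long "
      "recordings contribute many correlated windows.")
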