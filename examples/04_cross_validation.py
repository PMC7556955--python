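"""Pairs-mode cross-validation: full pipeline vs. the plain-CMF baseline.

Each fold masks a fifth of the known association pairs, re-runs every
MD-dependent stage (GIP kernels, WKNKN, CMF) on the masked matrix, and ranks
the held-out pairs against all non-associations. Disabling completion and
WKNKN gives the unaided collaborative-matrix-factorization baseline.
"""

from mccmf import RunConfig, SyntheticConfig, make_cv_plan, make_problem, run_cv

md, mf, ds, _ = make_problem(SyntheticConfig(nm=100, nd=60, density=0.12, seed=7))
plan = make_cv_plan(md, folds=5, repeats=2, seed=0)

full = run_cv(md, mf, ds, RunConfig(), plan)
base = run_cv(
    md, mf, ds, RunConfig(enable_completion=False, enable_wknkn=False), plan
)

print(f"full pipeline : AUC {full.auc_mean:.4f} +/- {full.auc_std:.4f}")
print(f"plain CMF     : AUC {base.auc_mean:.4f} +/- {base.auc_std:.4f}")
print(f"threshold {full.threshold:.3f}: accuracy {full.accuracy:.3f}, "
      f"precision {full.precision:.3f}, recall {full.recall:.3f}, "
      f"f-measure {full.f_measure:.3f}")
# AUC ~0.95 on planted data means held-out true pairs rank above ~95% of
# non-associations; the gap to the baseline is the value added by
# similarity denoising + neighbor pre-imputation.
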