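"""End-to-end orchestration: similarities -> completion -> integration ->
WKNKN -> collaborative matrix factorization -> scores.

Stage toggles allow ablations: with completion and WKNKN disabled the
pipeline degrades to the plain similarity-regularized CMF baseline. The
completed similarity matrices depend only on MF/DS, never on the association
matrix, so they can be computed once and reused across cross-validation
folds without information leakage; everything that touches MD (GIP kernels,
WKNKN, CMF) is recomputed from whatever matrix is passed in.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from ._types import (
    AssociationMatrix,
    DiseaseDAGCollection,
    PredictionMatrix,
    SimilarityMatrix,
)
from .cmf import CmfParams, fit_cmf, predict_scores
from .completion import CompletionParams, complete_similarity
from .preprocessing import WknknParams, integrate_similarity, wknkn
from .similarity import GipParams, SemanticParams, disease_semantic_similarity, gip_kernel

logger = logging.getLogger("mccmf")

__all__ = ["RunConfig", "StaticSimilarities", "prepare_static", "score_associations", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: per-stage parameters plus stage toggles."""

    semantic: SemanticParams = field(default_factory=SemanticParams)
    gip: GipParams = field(default_factory=GipParams)
    completion: CompletionParams = field(default_factory=CompletionParams)
    wknkn: WknknParams = field(default_factory=WknknParams)
    cmf: CmfParams = field(default_factory=CmfParams)
    enable_completion: bool = True
    enable_wknkn: bool = True
    enable_gip: bool = True
    threshold: float | None = None
    seed: int = 0


@dataclass
class StaticSimilarities:
    """MD-independent intermediates, safe to share across CV folds."""

    cm: SimilarityMatrix | None
    cd: SimilarityMatrix | None
    diagnostics: dict = field(default_factory=dict)


def prepare_static(
    mf: SimilarityMatrix, ds: SimilarityMatrix, config: RunConfig
) -> StaticSimilarities:
    """Run the completion stage (if enabled) on MF and DS."""
    if not config.enable_completion:
        return StaticSimilarities(cm=None, cd=None)
    t0 = time.perf_counter()
    cm, res_m = complete_similarity(
        SimilarityMatrix(mf.values, mf.ids, "MF"), config.completion
    )
    cd, res_d = complete_similarity(
        SimilarityMatrix(ds.values, ds.ids, "DS"), config.completion
    )
    diag = {
        "cm_iterations": res_m.iterations,
        "cm_converged": res_m.converged,
        "cd_iterations": res_d.iterations,
        "cd_converged": res_d.converged,
        "completion_seconds": time.perf_counter() - t0,
    }
    logger.info(
        "completion: CM %dx%d (%d it), CD %dx%d (%d it)",
        cm.n, cm.n, res_m.iterations, cd.n, cd.n, res_d.iterations,
    )
    return StaticSimilarities(cm=cm, cd=cd, diagnostics=diag)


def _integrate(
    completed: SimilarityMatrix | None,
    gip: SimilarityMatrix | None,
    original: SimilarityMatrix,
    role: str,
) -> SimilarityMatrix:
    """Three-way integration, degrading gracefully when stages are disabled.

    With both auxiliary sources present this is the standard rule (average
    of completed and GIP where the original is 0, three-way average
    elsewhere); with one source, the two-way analogue; with none, the
    original is passed through.
    """
    if completed is not None and gip is not None:
        return integrate_similarity(completed, gip, original)
    aux = completed if completed is not None else gip
    if aux is None:
        return SimilarityMatrix(original.values, list(original.ids), role)
    S, X = original.values, aux.values
    fused = np.where(S == 0.0, X, (X + S) / 2.0)
    return SimilarityMatrix(fused, list(original.ids), role)


def score_associations(
    md: AssociationMatrix,
    mf: SimilarityMatrix,
    ds: SimilarityMatrix,
    config: RunConfig = RunConfig(),
    static: StaticSimilarities | None = None,
    return_intermediates: bool = False,
):
    """Score all miRNA-disease pairs from a (possibly masked) MD.

    ``static`` carries precomputed completed similarities; when omitted they
    are computed here. Returns a :class:`PredictionMatrix`, plus a dict of
    intermediates when requested.
    """
    if mf.ids != md.mirna_ids:
        raise ValueError("MF labels do not match MD rows")
    if ds.ids != md.disease_ids:
        raise ValueError("DS labels do not match MD columns")
    static = static if static is not None else prepare_static(mf, ds, config)
    gm = gd = None
    if config.enable_gip:
        gm = gip_kernel(md, "mirna", config.gip)
        gd = gip_kernel(md, "disease", config.gip)
    ims = _integrate(static.cm, gm, mf, "IMS")
    ids_sim = _integrate(static.cd, gd, ds, "IDS")
    if config.enable_wknkn:
        pmd = wknkn(md, ims, ids_sim, config.wknkn).values
    else:
        pmd = md.values.astype(float)
    model = fit_cmf(
        pmd, ims.values, ids_sim.values, config.cmf,
        mirna_ids=md.mirna_ids, disease_ids=md.disease_ids,
    )
    pred = predict_scores(model)
    if return_intermediates:
        return pred, {
            "GM": gm, "GD": gd, "IMS": ims, "IDS": ids_sim,
            "PMD": pmd, "model": model,
        }
    return pred


def run_pipeline(
    md: AssociationMatrix,
    mf: SimilarityMatrix,
    ds: SimilarityMatrix | DiseaseDAGCollection,
    config: RunConfig = RunConfig(),
) -> tuple[PredictionMatrix, dict]:
    """Execute the full pipeline and return scores plus stage diagnostics."""
    t_start = time.perf_counter()
    diagnostics: dict = {"stages": []}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        diagnostics["stages"].append({"name": name, "seconds": round(dt, 4)})
        logger.info("stage %-12s %6.2fs", name, dt)
        return out

    if isinstance(ds, DiseaseDAGCollection):
        ds = stage("semantic", lambda: disease_semantic_similarity(ds, config.semantic))
    static = stage("completion", lambda: prepare_static(mf, ds, config))
    diagnostics.update(static.diagnostics)
    pred, inter = stage(
        "scoring",
        lambda: score_associations(
            md, mf, ds, config, static=static, return_intermediates=True
        ),
    )
    model = inter["model"]
    diagnostics.update(
        {
            "cmf_sweeps": model.n_iter,
            "cmf_converged": model.converged,
            "cmf_objective": model.objective_trace[-1],
            "total_seconds": round(time.perf_counter() - t_start, 4),
            "shape": [md.nm, md.nd],
        }
    )
    diagnostics["intermediates"] = inter
    return pred, diagnostics
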