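"""Difference tests between overlapping phenotype definitions.

Because every phenotype is defined on the same cohort (and every GWAS on
the same SNP panel), naive difference SEs would ignore the near-total
sampling overlap. All differences therefore come from a delete-one-block
jackknife on a *shared* partition: one seeded shuffle fixes contiguous
blocks along the resampled axis (individuals for heritability, SNPs for
genetic correlations), each estimate is recomputed on every leave-one-
block-out replicate, and the difference SE is taken over the paired
replicate differences. Group summaries pool member differences by
inverse-variance weighting; two-sided normal p-values are used throughout
(200 blocks make the normal reference adequate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .phenogrid import PhenotypePair

__all__ = [
    "JackknifeResult",
    "IVWGroupSummary",
    "BlockEstimate",
    "make_blocks",
    "jackknife_replicates",
    "difference_from_replicates",
    "jackknife_difference",
    "ivw_pool",
    "enrichment_trend",
    "component_attribution",
    "bonferroni",
]


class ComparisonError(ValueError):
    """Invalid comparison inputs."""


@dataclass
class JackknifeResult:
    delta: float
    se: float
    p: float
    n_blocks: int
    block_axis: str = "individuals"


@dataclass
class IVWGroupSummary:
    group: str
    mean_delta: float
    se: float
    p: float
    n_members: int


@dataclass
class BlockEstimate:
    """A full-sample estimate with its leave-one-block-out replicates."""

    name: str
    value: float
    replicates: np.ndarray
    enrichment: int = 0


def _norm_p(delta: float, se: float) -> float:
    if se == 0:
        return 1.0 if delta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(delta) / se))


def make_blocks(axis_len: int, n_blocks: int, seed: int) -> List[np.ndarray]:
    """Contiguous blocks of one seeded shuffle of the axis indices.

    The same partition must be reused for every estimate entering a
    difference, so that the sampling covariance of the overlapping samples
    propagates into the difference SE.
    """
    if n_blocks < 2:
        raise ComparisonError("n_blocks must be >= 2")
    if n_blocks > axis_len:
        raise ComparisonError("n_blocks exceeds the axis length")
    perm = np.random.default_rng(seed).permutation(axis_len)
    return [b for b in np.array_split(perm, n_blocks)]


def jackknife_replicates(
    estimator: Callable[[object, np.ndarray], float],
    data: object,
    blocks: Sequence[np.ndarray],
) -> BlockEstimate:
    """Full-sample estimate plus one estimate per leave-one-block-out subset.

    ``estimator(data, keep_idx)`` must be a deterministic function of the
    kept axis indices.
    """
    axis_len = sum(len(b) for b in blocks)
    all_idx = np.sort(np.concatenate(blocks))
    full = float(estimator(data, all_idx))
    reps = np.empty(len(blocks))
    for i, b in enumerate(blocks):
        keep = np.setdiff1d(all_idx, b, assume_unique=False)
        reps[i] = estimator(data, keep)
    return BlockEstimate(name="", value=full, replicates=reps)


def difference_from_replicates(
    ref: BlockEstimate, enr: BlockEstimate, block_axis: str = "individuals"
) -> JackknifeResult:
    """Jackknife difference (enriched - reference) from shared-block replicates."""
    if ref.replicates.shape != enr.replicates.shape:
        raise ComparisonError("replicates were not computed on a shared partition")
    d = enr.replicates - ref.replicates
    ok = np.isfinite(d)
    B = int(ok.sum())
    if B < 2:
        raise ComparisonError("fewer than 2 finite replicate differences")
    d = d[ok]
    se = float(np.sqrt((B - 1) / B * ((d - d.mean()) ** 2).sum()))
    delta = enr.value - ref.value
    return JackknifeResult(
        delta=float(delta), se=se, p=_norm_p(delta, se), n_blocks=B,
        block_axis=block_axis,
    )


def jackknife_difference(
    estimator: Callable[[object, np.ndarray], float],
    data_ref: object,
    data_enr: object,
    axis_len: int,
    n_blocks: int = 200,
    seed: int = 0,
    block_axis: str = "individuals",
) -> JackknifeResult:
    """Block-jackknife difference of one estimator applied to two datasets
    sharing the same axis (and hence the same seeded block partition)."""
    blocks = make_blocks(axis_len, n_blocks, seed)
    ref = jackknife_replicates(estimator, data_ref, blocks)
    enr = jackknife_replicates(estimator, data_enr, blocks)
    return difference_from_replicates(ref, enr, block_axis=block_axis)


def ivw_pool(deltas: Sequence[float], ses: Sequence[float]) -> IVWGroupSummary:
    """Fixed-effect inverse-variance-weighted mean of member differences."""
    d = np.asarray(deltas, dtype=np.float64)
    s = np.asarray(ses, dtype=np.float64)
    if d.size == 0:
        return IVWGroupSummary("", float("nan"), float("nan"), float("nan"), 0)
    if np.any(s < 0):
        raise ComparisonError("IVW pooling requires non-negative SEs")
    if np.any(s == 0):
        # infinite-weight members dominate (degenerate but exact estimates)
        d0 = d[s == 0]
        mean = float(d0.mean())
        return IVWGroupSummary("", mean, 0.0, _norm_p(mean, 0.0), int(d.size))
    w = 1.0 / (s * s)
    mean = float((w * d).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return IVWGroupSummary("", mean, se, _norm_p(mean, se), int(d.size))


def enrichment_trend(
    estimates: Iterable[BlockEstimate],
    reference_name: str = "Cardinal",
) -> List[IVWGroupSummary]:
    """Differences of every phenotype against the cardinal-only reference,
    pooled by enrichment level.

    The reference's own level is reported as zero by definition. Members
    with non-finite estimates are skipped.
    """
    ests = list(estimates)
    by_name = {e.name: e for e in ests}
    if reference_name not in by_name:
        raise ComparisonError(f"reference phenotype {reference_name!r} missing")
    ref = by_name[reference_name]

    groups: Dict[int, List[JackknifeResult]] = {}
    for e in ests:
        if e.name == reference_name:
            continue
        if not (np.isfinite(e.value) and np.isfinite(ref.value)):
            continue
        try:
            res = difference_from_replicates(ref, e)
        except ComparisonError:
            continue  # unestimable member: missing, never zero
        groups.setdefault(e.enrichment, []).append(res)

    out = [
        IVWGroupSummary(
            group=f"enrichment={ref.enrichment}", mean_delta=0.0, se=0.0,
            p=1.0, n_members=1,
        )
    ]
    for level in sorted(groups):
        pooled = ivw_pool([r.delta for r in groups[level]], [r.se for r in groups[level]])
        pooled.group = f"enrichment={level}"
        out.append(pooled)
    return out


def component_attribution(
    estimates: Iterable[BlockEstimate],
    pairs: Sequence[PhenotypePair],
) -> Dict[str, List[IVWGroupSummary]]:
    """Attribute estimate changes to the single component added in each pair.

    Returns ``{"cells": [...], "overall": [...]}``: one IVW summary per
    (component, base-enrichment) cell — 25 on the full grid — plus one
    overall IVW summary per component across all its pairs. Pairs whose
    members are degenerate (non-finite estimates) are dropped; a cell with
    no estimable members is reported with NaN, never zero.
    """
    by_name = {e.name: e for e in estimates}
    cells: Dict[tuple, List[JackknifeResult]] = {}
    overall: Dict[str, List[JackknifeResult]] = {}
    cell_keys = sorted({(p.added_component, p.base_enrichment) for p in pairs})
    for p in pairs:
        base = by_name.get(p.base.name)
        enr = by_name.get(p.enriched.name)
        if base is None or enr is None:
            raise ComparisonError(f"pair member missing from estimates: {p}")
        if not (np.isfinite(base.value) and np.isfinite(enr.value)):
            continue
        try:
            res = difference_from_replicates(base, enr)
        except ComparisonError:
            continue

        cells.setdefault((p.added_component, p.base_enrichment), []).append(res)
        overall.setdefault(p.added_component, []).append(res)

    cell_out = []
    for key in cell_keys:
        members = cells.get(key, [])
        pooled = ivw_pool([r.delta for r in members], [r.se for r in members])
        pooled.group = f"{key[0]}@enrichment={key[1]}"
        cell_out.append(pooled)
    overall_out = []
    for comp in sorted({p.added_component for p in pairs}):
        members = overall.get(comp, [])
        pooled = ivw_pool([r.delta for r in members], [r.se for r in members])
        pooled.group = comp
        overall_out.append(pooled)
    return {"cells": cell_out, "overall": overall_out}


def bonferroni(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ComparisonError("alpha must be in (0,1)")
    if n_tests < 1:
        raise ComparisonError("n_tests must be >= 1")
    return alpha / n_tests
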