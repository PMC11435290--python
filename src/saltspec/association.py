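"""Marker-trait association by stepwise multiple linear regression.

Genotype-mean traits or spectral indices are regressed on binary SSR
predictors. Forward steps enter the candidate with the smallest partial-F
p-value below ``alpha_enter``; after each entry, any previously entered marker
whose drop-test p-value exceeds ``alpha_remove`` is removed (bidirectional
stepwise). The per-marker partial R-squared is the increase in model
R-squared at the step the marker entered, so the partials add up exactly to
the cumulative R-squared, matching the usual "R2 partial / R2 cumulative"
association-table layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, SaltspecError

logger = logging.getLogger(__name__)


@dataclass
class StepwiseResult:
    """Selected markers in entry order with their partial and cumulative R2."""

    response: str
    markers: list[str] = field(default_factory=list)
    partial_r2: list[float] = field(default_factory=list)
    p_values: dict[str, float] = field(default_factory=dict)  # final-model drop tests
    n: int = 0

    @property
    def cumulative_r2(self) -> float:
        return float(sum(self.partial_r2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "response": self.response,
            "marker": self.markers,
            "partial_r2": self.partial_r2,
            "cumulative_r2": np.cumsum(self.partial_r2),
            "p_value": [self.p_values.get(m, np.nan) for m in self.markers],
        })


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of [1 | X]."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, residuals, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    return float(np.sum((y - fitted) ** 2)), int(rank)


def stepwise_marker_selection(
    y: pd.Series,
    markers: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_steps: int | None = None,
) -> StepwiseResult:
    """Bidirectional stepwise selection of markers for one response.

    ``y`` is indexed by genotype and must align with the marker matrix rows.
    Candidates perfectly collinear with the entered set are skipped (logged).
    Entry stops when no candidate reaches ``alpha_enter``, when residual
    degrees of freedom run out, or after ``max_steps`` entries.
    """
    if not y.index.equals(markers.index):
        if set(y.index) != set(markers.index):
            raise AlignmentError("response and marker matrix genotypes differ")
        markers = markers.loc[y.index]
    yv = y.to_numpy(float)
    n = len(yv)
    ss_total = float(np.sum((yv - yv.mean()) ** 2))
    if ss_total == 0:
        raise SaltspecError(f"response {y.name!r} has zero variance")
    if max_steps is None:
        max_steps = markers.shape[1]

    entered: list[str] = []
    partial: list[float] = []
    result = StepwiseResult(response=str(y.name), n=n)

    def model_sse(cols: list[str]) -> tuple[float, int]:
        return _sse(markers[cols].to_numpy(float), yv)

    sse_current, rank_current = ss_total, 1
    while len(entered) < max_steps:
        if sse_current <= 1e-12 * ss_total:  # already a perfect fit
            break
        df_resid_next = n - (rank_current + 1)
        if df_resid_next < 1:
            break
        best: tuple[float, str, float, float] | None = None  # (p, name, sse, r2_gain)
        for cand in markers.columns:
            if cand in entered:
                continue
            sse_new, rank_new = model_sse(entered + [cand])
            if rank_new == rank_current:  # perfectly confounded with entered set
                logger.info("candidate %s collinear with entered set; skipped", cand)
                continue
            df_resid = n - rank_new
            if df_resid < 1:
                continue
            f = (sse_current - sse_new) / (sse_new / df_resid) if sse_new > 0 else np.inf
            p = 0.0 if not np.isfinite(f) else float(stats.f.sf(f, 1, df_resid))
            gain = (sse_current - sse_new) / ss_total
            if best is None or p < best[0] - 1e-15 or (abs(p - best[0]) <= 1e-15
                                                       and gain > best[3]):
                best = (p, cand, sse_new, gain)
        if best is None or best[0] >= alpha_enter:
            break
        p, name, sse_new, gain = best
        entered.append(name)
        partial.append(gain)
        sse_current = sse_new
        rank_current += 1
        # backward pass: drop any entered marker that no longer earns its keep
        changed = True
        while changed and len(entered) > 1:
            changed = False
            drop_p: list[tuple[float, str]] = []
            for m in entered:
                reduced = [e for e in entered if e != m]
                sse_red, _ = model_sse(reduced)
                df_resid = n - rank_current
                f = (sse_red - sse_current) / (sse_current / df_resid) \
                    if sse_current > 0 else np.inf
                pm = 0.0 if not np.isfinite(f) else float(stats.f.sf(f, 1, df_resid))
                drop_p.append((pm, m))
            worst_p, worst = max(drop_p)
            if worst_p > alpha_remove and worst != name:
                entered.remove(worst)
                # rebuild partial R2 as sequential gains along the entry order,
                # so the partials still sum exactly to the model R2
                partial, prev_sse = [], ss_total
                for depth in range(1, len(entered) + 1):
                    sse_k, _ = model_sse(entered[:depth])
                    partial.append((prev_sse - sse_k) / ss_total)
                    prev_sse = sse_k
                sse_current, rank_current = model_sse(entered)
                changed = True
    # final-model drop-test p-values
    df_resid = n - rank_current
    for m in entered:
        reduced = [e for e in entered if e != m]
        sse_red, _ = model_sse(reduced)
        f = (sse_red - sse_current) / (sse_current / df_resid) if sse_current > 0 else np.inf
        result.p_values[m] = 0.0 if not np.isfinite(f) else float(stats.f.sf(f, 1, df_resid))
    result.markers = entered
    result.partial_r2 = partial
    return result


def association_table(
    responses: pd.DataFrame,
    markers: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> pd.DataFrame:
    """Stepwise association of every numeric response column with the markers."""
    frames = []
    for col in responses.select_dtypes("number").columns:
        res = stepwise_marker_selection(responses[col], markers,
                                        alpha_enter, alpha_remove)
        if res.markers:
            frames.append(res.to_frame())
    if not frames:
        return pd.DataFrame(
            columns=["response", "marker", "partial_r2", "cumulative_r2", "p_value"])
    return pd.concat(frames, ignore_index=True)
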