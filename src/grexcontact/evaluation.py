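"""Scoring of trained contact-frequency models.

Covers per-pair relative error E = |ŷ − y| / y (defined for y > 0, which
the min-contact filter guarantees), exact two-feature Shapley attribution
(the four-coalition closed form, with the local-accuracy identity asserted
per instance), cross-tissue transfer R², and the Pearson correlation of
genomic distance with predicted and observed contact frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .contact_models import PredictionVector, TrainedModel, evaluate_r2
from .contact_pairs import PairDataset


@dataclass
class RelativeErrorReport:
    median_e: float
    best_pair: Tuple[str, str, float]   # (upstream, downstream, E)
    worst_pair: Tuple[str, str, float]
    errors: pd.DataFrame                # upstream_id, downstream_id, y, yhat, e


@dataclass
class AttributionReport:
    """Mean |Shapley value| per feature and relative contributions (%)."""

    mean_abs_phi_up: float
    mean_abs_phi_down: float
    contribution_up_pct: float
    contribution_down_pct: float
    phi: np.ndarray  # instances × 2

    def __post_init__(self) -> None:
        total = self.contribution_up_pct + self.contribution_down_pct
        if not np.isclose(total, 100.0, atol=1e-9):
            raise ValueError(f"contributions must sum to 100, got {total}")


def relative_error_stats(
    observed: Union[np.ndarray, Sequence[float]],
    predicted: Union[np.ndarray, Sequence[float]],
    upstream_ids: Optional[Sequence[str]] = None,
    downstream_ids: Optional[Sequence[str]] = None,
) -> RelativeErrorReport:
    """Median relative error with best- and worst-predicted pairs.

    Raises if any observed contact is ≤ 0, identifying the offending pairs.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0:
        raise ValueError("no predictions to score")
    n = y.size
    up = list(upstream_ids) if upstream_ids is not None else [f"pair{i}" for i in range(n)]
    down = list(downstream_ids) if downstream_ids is not None else [""] * n
    if (y <= 0).any():
        bad = [up[i] for i in np.flatnonzero(y <= 0)[:5]]
        raise ValueError(f"relative error undefined for observed ≤ 0 (e.g. {bad})")
    e = np.abs(yhat - y) / y
    errors = pd.DataFrame({"upstream_id": up, "downstream_id": down,
                           "observed": y, "predicted": yhat, "e": e})
    i_best, i_worst = int(np.argmin(e)), int(np.argmax(e))
    return RelativeErrorReport(
        median_e=float(np.median(e)),
        best_pair=(up[i_best], down[i_best], float(e[i_best])),
        worst_pair=(up[i_worst], down[i_worst], float(e[i_worst])),
        errors=errors,
    )


def shap_two_feature(
    model,
    data: Union[PairDataset, np.ndarray],
    background: Optional[np.ndarray] = None,
) -> AttributionReport:
    """Exact Shapley attribution for a two-feature model.

    With features (x₁, x₂) and background (b₁, b₂):
        φ₁ = ½[(f(x₁,b₂) − f(b₁,b₂)) + (f(x₁,x₂) − f(b₁,x₂))]
        φ₂ = ½[(f(b₁,x₂) − f(b₁,b₂)) + (f(x₁,x₂) − f(x₁,b₂))]
    Local accuracy φ₁ + φ₂ = f(x) − f(b) holds identically and is asserted
    per instance. Relative contribution_i = mean|φ_i| / Σ mean|φ_j| × 100.
    The default background is the per-feature mean of ``data``.
    """
    if isinstance(data, PairDataset):
        X = data.features()
    else:
        X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("exact two-feature attribution requires exactly 2 features")
    if getattr(model, "n_features", 2) != 2:
        raise ValueError("model must take exactly 2 features")
    b = np.asarray(background, dtype=float) if background is not None else X.mean(axis=0)
    if b.shape != (2,):
        raise ValueError("background must be a length-2 vector")

    f = model.predict
    n = X.shape[0]
    B = np.broadcast_to(b, (n, 2)).copy()
    X1b2 = np.column_stack([X[:, 0], B[:, 1]])
    B1x2 = np.column_stack([B[:, 0], X[:, 1]])
    f_xx = f(X)
    f_bb = f(B)
    f_xb = f(X1b2)
    f_bx = f(B1x2)
    phi1 = 0.5 * ((f_xb - f_bb) + (f_xx - f_bx))
    phi2 = 0.5 * ((f_bx - f_bb) + (f_xx - f_xb))
    resid = np.abs(phi1 + phi2 - (f_xx - f_bb))
    if resid.max() > 1e-9:
        raise AssertionError(f"local accuracy violated: max residual {resid.max():.3e}")
    m1, m2 = float(np.abs(phi1).mean()), float(np.abs(phi2).mean())
    total = m1 + m2
    if total == 0:
        c1 = c2 = 50.0
    else:
        c1, c2 = 100.0 * m1 / total, 100.0 * m2 / total
    return AttributionReport(m1, m2, c1, c2, np.column_stack([phi1, phi2]))


def cross_tissue_transfer(model: TrainedModel, foreign: PairDataset) -> float:
    """Apply a model (with its stored training-tissue feature scaling) to a
    previously unseen tissue's pair data; returns the R²."""
    needed = 3 if model.architecture.n_inputs == 3 else 2
    X = foreign.features(with_distance=needed == 3)
    if X.shape[1] != model.n_features:
        raise ValueError("foreign dataset feature schema does not match model")
    return evaluate_r2(PredictionVector(foreign.contact, model.predict(X)))


@dataclass
class DistanceCorrelation:
    r_predicted: float
    r_observed: float
    predicted_degenerate: bool = False
    observed_degenerate: bool = False


def _pearson(x: np.ndarray, y: np.ndarray) -> Tuple[float, bool]:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0, True
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return r, False


def distance_contact_correlation(
    observed: np.ndarray,
    predicted: np.ndarray,
    log1p_distance: np.ndarray,
) -> DistanceCorrelation:
    """Pearson r of log1p genomic distance with predicted and observed
    contact. Degenerate (zero-variance) inputs report r = 0 with a flag
    rather than NaN."""
    d = np.asarray(log1p_distance, float)
    y = np.asarray(observed, float)
    yhat = np.asarray(predicted, float)
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    r_pred, deg_p = _pearson(d, yhat)
    r_obs, deg_o = _pearson(d, y)
    return DistanceCorrelation(r_pred, r_obs, deg_p, deg_o)
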