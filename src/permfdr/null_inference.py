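"""Logistic-model inference of null distributions from sample features.

For each score bin k, the cumulative null probability of sample i,
Pr_{i,k} = Pr(x <= upper edge of bin k), is related to the sample's
features r_{i,1..J} through a per-bin logistic model

    logit(Pr_{i,k}) = beta_{k,0} + sum_j beta_{k,j} r_{i,j}.

Fitting is least squares on the logit scale (not binomial maximum
likelihood): the coefficients minimize
sum_i L(logit(Pr_{i,k}) - beta_{k,0} - sum_j beta_{k,j} r_{i,j}),
with L the squared error by default and the Huber loss selectable. The
last bin is skipped because Pr_{i,K} = 1 for every sample, so a fitted
coefficient table has exactly K-1 rows.

Given a new sample's features r_0, each bin's cumulative probability is
predicted by the logistic function and the null density recovered by
first differences, with Pr_0(bin 0) = 0 and Pr_0(bin K) = 1. Because the
per-bin fits are independent, the predicted cumulative sequence can be
non-monotone; it is repaired by isotonic (L2) projection before
differencing, which guarantees a non-negative density summing to 1.

Cumulative probabilities equal to 0 or 1 (unavoidable in empty leading
bins) are clipped into [clip_eps, 1 - clip_eps] before the logit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit
from sklearn.isotonic import IsotonicRegression

from .features import FeatureVector
from .null_model import NullDistribution

DEFAULT_CLIP_EPS = 1e-6
DEFAULT_NOMINAL_M = 1e6
LOSSES = ("l2", "huber")


@dataclass
class CoefficientTable:
    """Fitted per-bin logistic coefficients: (K-1) x (J+1) matrix.

    Row k-1 holds (beta_{k,0}, beta_{k,1..J}) for bin k; there is no row
    for the last bin.
    """

    beta: np.ndarray
    bin_width: float
    lo: float = 0.0
    hi: float = 1.0
    loss: str = "l2"
    clip_eps: float = DEFAULT_CLIP_EPS

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))

    @property
    def K(self) -> int:
        return self.beta.shape[0] + 1

    @property
    def J(self) -> int:
        return self.beta.shape[1] - 1

    def to_tsv(self, path: str | Path) -> None:
        """Write the coefficient rows as TSV plus a JSON metadata sidecar."""
        path = Path(path)
        cols = {"bin": np.arange(1, self.K)}
        cols["intercept"] = self.beta[:, 0]
        for j in range(1, self.J + 1):
            cols[f"feature_{j}"] = self.beta[:, j]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        meta = {
            "K": self.K,
            "J": self.J,
            "bin_width": self.bin_width,
            "lo": self.lo,
            "hi": self.hi,
            "loss": self.loss,
            "clip_eps": self.clip_eps,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoefficientTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        feature_cols = [c for c in df.columns if c.startswith("feature_")]
        beta = df[["intercept"] + feature_cols].to_numpy(dtype=float)
        return cls(
            beta=beta,
            bin_width=meta["bin_width"],
            lo=meta["lo"],
            hi=meta["hi"],
            loss=meta["loss"],
            clip_eps=meta["clip_eps"],
        )


def cum_prob(null: NullDistribution, k: int) -> float:
    """Pr(x <= upper edge of bin k) under the null; k is 1-based."""
    if not 1 <= k <= null.K:
        raise ValueError(f"bin index {k} out of range 1..{null.K}")
    if null.M == 0:
        raise ValueError("null distribution has no mass (M = 0)")
    return float(null.cum[k - 1])


def _clipped_logit(pr: np.ndarray, clip_eps: float) -> np.ndarray:
    return logit(np.clip(pr, clip_eps, 1.0 - clip_eps))


def fit_bin(
    r: np.ndarray,
    pr: np.ndarray,
    loss: str = "l2",
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> np.ndarray:
    """Fit one bin's coefficient row from I samples.

    ``r`` is the I x J feature matrix, ``pr`` the I cumulative
    probabilities for this bin. Returns (beta_0, beta_1..beta_J).
    """
    if loss not in LOSSES:
        raise ValueError(f"unknown loss {loss!r}; choose from {LOSSES}")
    if not 0 < clip_eps < 0.5:
        raise ValueError("clip_eps must lie in (0, 0.5)")
    r = np.atleast_2d(np.asarray(r, dtype=float))
    if r.shape[0] == 1 and len(np.asarray(pr)) > 1:
        r = r.T
    pr = np.asarray(pr, dtype=float)
    n_samples, n_features = r.shape
    if n_samples < n_features + 1:
        raise ValueError(
            f"underdetermined fit: {n_samples} samples for {n_features + 1} coefficients"
        )
    design = np.column_stack([np.ones(n_samples), r])
    if np.linalg.matrix_rank(design) < n_features + 1:
        raise ValueError("rank-deficient design (e.g. all feature vectors identical)")
    target = _clipped_logit(pr, clip_eps)
    beta_ls, *_ = np.linalg.lstsq(design, target, rcond=None)
    if loss == "l2":
        return beta_ls
    res = least_squares(
        lambda b: design @ b - target, x0=beta_ls, loss="huber", f_scale=1.0
    )
    return res.x


def fit_coefficient_table(
    nulls: list[NullDistribution],
    features: list[FeatureVector],
    loss: str = "l2",
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> CoefficientTable:
    """Fit the (K-1)-row coefficient table from stored nulls and features."""
    if len(nulls) != len(features):
        raise ValueError("nulls and features must have equal length")
    if not nulls:
        raise ValueError("at least one null distribution is required")
    first = nulls[0]
    for nd in nulls[1:]:
        if nd.K != first.K or nd.bin_width != first.bin_width or (nd.lo, nd.hi) != (first.lo, first.hi):
            raise ValueError("all nulls must share bin count, width and domain")
    r = np.vstack([f.r for f in features])
    cum = np.vstack([nd.cum for nd in nulls])  # I x K
    k_bins = first.K
    beta = np.empty((k_bins - 1, r.shape[1] + 1), dtype=float)
    for k in range(k_bins - 1):
        beta[k] = fit_bin(r, cum[:, k], loss=loss, clip_eps=clip_eps)
    return CoefficientTable(
        beta=beta,
        bin_width=first.bin_width,
        lo=first.lo,
        hi=first.hi,
        loss=loss,
        clip_eps=clip_eps,
    )


def predict_cum_prob(beta_row: np.ndarray, r0: FeatureVector | np.ndarray) -> float:
    """Logistic prediction of one bin's cumulative probability; in (0, 1)."""
    beta_row = np.asarray(beta_row, dtype=float)
    r = r0.r if isinstance(r0, FeatureVector) else np.atleast_1d(np.asarray(r0, dtype=float))
    if len(r) != len(beta_row) - 1:
        raise ValueError(f"feature vector length {len(r)} does not match J={len(beta_row) - 1}")
    lin = beta_row[0] + float(beta_row[1:] @ r)
    return float(expit(np.clip(lin, -700.0, 700.0)))


def infer_null(
    coeffs: CoefficientTable,
    r0: FeatureVector | np.ndarray,
    nominal_m: float = DEFAULT_NOMINAL_M,
) -> NullDistribution:
    """Reconstruct a new sample's null density from the coefficient table.

    Predicts the cumulative probability of each of the first K-1 bins,
    forces the last to 1, isotonically repairs any non-monotonicity, and
    differences to a density. The returned distribution carries fractional
    counts at a nominal total mass ``nominal_m`` so that downstream
    p-value computation works unchanged.
    """
    cum = np.array(
        [predict_cum_prob(row, r0) for row in coeffs.beta] + [1.0], dtype=float
    )
    if np.any(np.diff(cum) < 0):
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
        cum = iso.fit_transform(np.arange(len(cum)), cum)
        cum[-1] = 1.0
    density = np.diff(cum, prepend=0.0)
    return NullDistribution(
        counts=density * nominal_m,
        bin_width=coeffs.bin_width,
        lo=coeffs.lo,
        hi=coeffs.hi,
    )
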