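"""Per-sample features for similarity matching and null inference.

A sample's protein identification result is summarized by a 10-bin
histogram of its target protein scores on [0, 1]; the single feature of
the current implementation is the Kullback-Leibler divergence from that
histogram to the histogram of a designated reference sample:

    D(P || Q) = sum_k P_k log(P_k / Q_k)      (natural log)

KL is non-symmetric, so the choice of reference matters. Zero bins are
handled by adding a small pseudo-probability ``eps`` to every bin of
both histograms and renormalizing before the logarithm; two identical
histograms still give D = 0 exactly. All histograms share the fixed
[0, 1] domain so that cross-sample divergences are well defined.

Decoy entries are excluded: the features describe the sample's target
identification result, not its decoy search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .null_model import SampleScores

DEFAULT_N_FEATURE_BINS = 10
DEFAULT_KL_EPS = 1e-9


@dataclass
class ScoreHistogram:
    """Normalized bin probabilities of a sample's target protein scores."""

    probs: np.ndarray
    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ValueError("histogram probabilities must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.probs)


@dataclass
class FeatureVector:
    """Feature values r_1..r_J of one sample (current implementation J=1)."""

    sample_id: str
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))

    @property
    def J(self) -> int:
        return len(self.r)


def histogram_from_scores(
    scores,
    n_bins: int = DEFAULT_N_FEATURE_BINS,
    lo: float = 0.0,
    hi: float = 1.0,
) -> ScoreHistogram:
    """Equal-width histogram of raw scores, normalized to probabilities."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot build a histogram from zero scores")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    counts, _ = np.histogram(scores, bins=n_bins, range=(lo, hi))
    return ScoreHistogram(probs=counts / counts.sum(), lo=lo, hi=hi)


def score_histogram(
    sample: SampleScores,
    n_bins: int = DEFAULT_N_FEATURE_BINS,
    lo: float = 0.0,
    hi: float = 1.0,
) -> ScoreHistogram:
    """Histogram of a sample's target (non-decoy) protein scores."""
    scores = sample.target_scores()
    if scores.size == 0:
        raise ValueError(f"sample {sample.sample_id!r} has no target entries")
    return histogram_from_scores(scores, n_bins=n_bins, lo=lo, hi=hi)


def kl_divergence(
    P: ScoreHistogram,
    Q: ScoreHistogram,
    eps: float = DEFAULT_KL_EPS,
    base: float | None = None,
) -> float:
    """KL divergence D(P || Q) over eps-smoothed histograms, in nats.

    ``base`` switches the logarithm (e.g. 2); only relative comparisons
    matter for similarity, so the default natural log is conventional.
    """
    if P.n_bins != Q.n_bins or (P.lo, P.hi) != (Q.lo, Q.hi):
        raise ValueError("histograms must share bin count and domain")
    if eps <= 0:
        raise ValueError("eps must be positive")
    p = (P.probs + eps) / (P.probs + eps).sum()
    q = (Q.probs + eps) / (Q.probs + eps).sum()
    d = float(np.sum(p * np.log(p / q)))
    if base is not None:
        d /= np.log(base)
    # projection noise can leave a tiny negative residue when p == q
    return max(d, 0.0) if abs(d) < 1e-15 else d


def extract_feature(
    sample: SampleScores,
    reference: SampleScores,
    n_bins: int = DEFAULT_N_FEATURE_BINS,
    eps: float = DEFAULT_KL_EPS,
) -> FeatureVector:
    """The J=1 feature: KL divergence from ``sample`` to ``reference``."""
    p = score_histogram(sample, n_bins=n_bins)
    q = score_histogram(reference, n_bins=n_bins)
    return FeatureVector(sample_id=sample.sample_id, r=np.array([kl_divergence(p, q, eps=eps)]))
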