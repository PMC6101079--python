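"""Empirical null distributions of decoy protein scores.

The score of every protein identification mapping to a decoy sequence is a
draw from the false-positive (null) score distribution. Pooling decoy
scores across permutation repeats and binning them on the unit interval
gives a non-parametric estimate of the null density; the p-value of a
target protein is the null mass in its bin and all higher bins.

Scores are protein probabilities in [0, 1] (e.g. ProteinProphet output)
used as the test statistic. The default bin width is 0.003, which
partitions the unit interval into K = 334 bins, the last one truncated
(333 x 0.003 = 0.999, so bin 334 covers [0.999, 1]). Bins are half-open
[left, right) with the final bin right-closed, so every score in the
domain belongs to exactly one bin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fdr import PValueSet

DEFAULT_BIN_WIDTH = 0.003


@dataclass
class ProteinScore:
    """One inferred protein: accession, score in [0, 1], decoy flag."""

    accession: str
    score: float
    decoy: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"score {self.score} for {self.accession!r} outside [0, 1]"
            )


@dataclass
class SampleScores:
    """A sample's protein identification result."""

    sample_id: str
    entries: list[ProteinScore] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    def target_entries(self) -> list[ProteinScore]:
        return [e for e in self.entries if not e.decoy]

    def decoy_entries(self) -> list[ProteinScore]:
        return [e for e in self.entries if e.decoy]

    def target_scores(self) -> np.ndarray:
        return np.array([e.score for e in self.target_entries()], dtype=float)


def n_bins(lo: float, hi: float, bin_width: float) -> int:
    """Number of equal-length bins covering [lo, hi]: ceil((hi-lo)/w).

    A small tolerance guards against floating-point overshoot when the
    span is an exact multiple of the width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if bin_width > hi - lo:
        raise ValueError("bin_width exceeds the domain span")
    return int(math.ceil((hi - lo) / bin_width - 1e-9))


@dataclass
class NullDistribution:
    """Binned empirical density/CDF of decoy (false-positive) scores.

    ``counts`` is float64: integer-valued when built from observed decoy
    scores, possibly fractional when synthesized or inferred (exact mass
    at a nominal total M, avoiding quantization of the cumulative
    probabilities).
    """

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a non-empty 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected_k = n_bins(self.lo, self.hi, self.bin_width)
        if len(self.counts) != expected_k:
            raise ValueError(
                f"counts has {len(self.counts)} bins; "
                f"bin_width {self.bin_width} on [{self.lo}, {self.hi}] implies K={expected_k}"
            )

    @property
    def K(self) -> int:
        return len(self.counts)

    @property
    def M(self) -> float:
        return float(self.counts.sum())

    @property
    def edges(self) -> np.ndarray:
        """K+1 bin edges; the last bin may be narrower than bin_width."""
        e = self.lo + self.bin_width * np.arange(self.K + 1, dtype=float)
        e[-1] = self.hi
        return e

    @property
    def centers(self) -> np.ndarray:
        """Bin centers x_k (the last one is the center of the truncated bin)."""
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def density(self) -> np.ndarray:
        """y_k / M: non-negative, sums to 1 when M > 0."""
        if self.M == 0:
            raise ValueError("null distribution has no mass (M = 0)")
        return self.counts / self.M

    @property
    def cum(self) -> np.ndarray:
        """Cumulative probabilities P[k] = Pr(x <= upper edge of bin k)."""
        c = np.cumsum(self.density)
        c[-1] = 1.0
        return c

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lo": self.lo,
            "hi": self.hi,
            "bin_width": self.bin_width,
            "K": self.K,
            "M": self.M,
            "counts": self.counts.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NullDistribution":
        payload = json.loads(Path(path).read_text())
        return cls(
            counts=np.asarray(payload["counts"], dtype=float),
            bin_width=payload["bin_width"],
            lo=payload["lo"],
            hi=payload["hi"],
        )


def pool_decoy_scores(repeats: list[SampleScores]) -> np.ndarray:
    """Concatenate decoy scores across permutation repeats.

    The pooled vector (length M) is the raw material of the empirical
    null. Raises if no decoy score is found in any repeat ("empty null").
    """
    scores: list[float] = []
    for rep in repeats:
        scores.extend(e.score for e in rep.decoy_entries())
    if not scores:
        raise ValueError("empty null: no decoy scores found in any repeat")
    return np.asarray(scores, dtype=float)


def bin_index(score: float, null: NullDistribution) -> int:
    """1-based bin index of ``score``; the top edge maps to the last bin."""
    if not null.lo <= score <= null.hi:
        raise ValueError(f"score {score} outside [{null.lo}, {null.hi}]")
    k = int(math.floor((score - null.lo) / null.bin_width)) + 1
    return min(k, null.K)


def build_null(
    decoy_scores,
    bin_width: float = DEFAULT_BIN_WIDTH,
    lo: float = 0.0,
    hi: float = 1.0,
) -> NullDistribution:
    """Bin pooled decoy scores into an empirical null distribution."""
    scores = np.asarray(decoy_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot build a null from zero scores")
    if np.any((scores < lo) | (scores > hi)):
        raise ValueError(f"scores outside the domain [{lo}, {hi}]")
    k = n_bins(lo, hi, bin_width)
    edges = lo + bin_width * np.arange(k + 1, dtype=float)
    edges[-1] = hi
    counts, _ = np.histogram(scores, bins=edges)
    return NullDistribution(counts=counts.astype(float), bin_width=bin_width, lo=lo, hi=hi)


def pvalue(null: NullDistribution, score: float, conservative: bool = False) -> float:
    """Bin-based p-value: null mass in the score's bin and all higher bins.

    With ``conservative=True`` the estimate is floored away from zero as
    (tail count + 1) / (M + 1), useful when a score exceeds every decoy.
    """
    if null.M == 0:
        raise ValueError("null distribution has no mass (M = 0)")
    k_hat = bin_index(score, null)
    tail = float(null.counts[k_hat - 1:].sum())
    if conservative:
        return (tail + 1.0) / (null.M + 1.0)
    return tail / null.M


def pvalues(
    null: NullDistribution, sample: SampleScores, conservative: bool = False
) -> PValueSet:
    """p-values for every target (non-decoy) entry, in input order."""
    targets = sample.target_entries()
    if not targets:
        raise ValueError(f"sample {sample.sample_id!r} has no target entries")
    p = [pvalue(null, e.score, conservative=conservative) for e in targets]
    return PValueSet(
        sample_id=sample.sample_id,
        accessions=[e.accession for e in targets],
        p=np.asarray(p, dtype=float),
    )


# -- score-table I/O ---------------------------------------------------------

def read_scores_tsv(
    path: str | Path,
    sample_id: str | None = None,
    decoy_prefix: str | None = None,
) -> SampleScores:
    """Read a score table: TSV with columns accession, score, decoy (0/1).

    If the ``decoy`` column is absent, ``decoy_prefix`` is used to flag
    decoys by accession (the FASTA convention of :mod:`permfdr.seqdb`).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"accession", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} lacks required columns {sorted(required)}")
    if "decoy" in df.columns:
        decoy = df["decoy"].astype(int).astype(bool)
    elif decoy_prefix is not None:
        decoy = df["accession"].astype(str).str.startswith(decoy_prefix)
    else:
        decoy = pd.Series(False, index=df.index)
    entries = [
        ProteinScore(accession=str(a), score=float(s), decoy=bool(d))
        for a, s, d in zip(df["accession"], df["score"], decoy)
    ]
    return SampleScores(sample_id=sample_id or path.stem, entries=entries)


def write_scores_tsv(sample: SampleScores, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "accession": [e.accession for e in sample.entries],
            "score": [e.score for e in sample.entries],
            "decoy": [int(e.decoy) for e in sample.entries],
        }
    )
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
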