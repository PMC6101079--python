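"""The feature protein database and its resolve workflow.

A feature database persists everything needed to estimate protein-level
FDR for a new sample without re-running permutations: the stored null
distributions of previously analyzed samples, their feature table, the
fitted coefficient table, and the reference sample's score histogram
(so feature extraction for new samples never re-reads the reference's
raw scores).

Resolving a new sample follows the off-line decision workflow: extract
the sample's feature (KL divergence to the reference); if a stored
sample is similar enough, reuse its null unchanged; otherwise infer a
new null from the coefficient table.

Similarity: with J >= 2 features, Pearson correlation of feature
vectors above a threshold (default 0.9). With the J = 1 feature of the
current implementation correlation is undefined, so similarity is the
absolute feature difference against a tolerance (default 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .features import (
    DEFAULT_KL_EPS,
    DEFAULT_N_FEATURE_BINS,
    FeatureVector,
    ScoreHistogram,
    kl_divergence,
    score_histogram,
)
from .null_inference import CoefficientTable, infer_null
from .null_model import NullDistribution, SampleScores

SCHEMA_VERSION = 1
DEFAULT_CORR_THRESHOLD = 0.9
DEFAULT_FEATURE_TOLERANCE = 0.05


@dataclass
class DbConfig:
    bin_width: float = 0.003
    lo: float = 0.0
    hi: float = 1.0
    n_feature_bins: int = DEFAULT_N_FEATURE_BINS
    corr_threshold: float = DEFAULT_CORR_THRESHOLD
    feature_tolerance: float = DEFAULT_FEATURE_TOLERANCE
    kl_eps: float = DEFAULT_KL_EPS


@dataclass
class FeatureDatabase:
    """Stored nulls + feature table + coefficient table + reference."""

    protein_db_path: str
    stored_nulls: dict[str, NullDistribution]
    feature_table: list[FeatureVector]
    reference_sample_id: str
    reference_histogram: ScoreHistogram
    coefficients: CoefficientTable | None = None
    coefficients_stale: bool = False
    config: DbConfig = field(default_factory=DbConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for fv in self.feature_table:
            if fv.sample_id not in self.stored_nulls:
                raise ValueError(
                    f"feature table sample {fv.sample_id!r} has no stored null"
                )
        ks = {nd.K for nd in self.stored_nulls.values()}
        if len(ks) > 1:
            raise ValueError(f"stored nulls disagree on bin count: {sorted(ks)}")
        if self.coefficients is not None and self.stored_nulls:
            k = next(iter(ks))
            if self.coefficients.K != k:
                raise ValueError(
                    f"coefficient table K={self.coefficients.K} does not match stored nulls K={k}"
                )
            js = {fv.J for fv in self.feature_table}
            if js and self.coefficients.J not in js:
                raise ValueError("coefficient table J does not match feature table")

    def features_of(self, sample_id: str) -> FeatureVector:
        for fv in self.feature_table:
            if fv.sample_id == sample_id:
                return fv
        raise KeyError(sample_id)


def save_db(db: FeatureDatabase, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "protein_db_path": db.protein_db_path,
        "reference_sample_id": db.reference_sample_id,
        "reference_histogram": {
            "probs": db.reference_histogram.probs.tolist(),
            "lo": db.reference_histogram.lo,
            "hi": db.reference_histogram.hi,
        },
        "config": vars(db.config),
        "stored_nulls": {
            sid: {
                "counts": nd.counts.tolist(),
                "bin_width": nd.bin_width,
                "lo": nd.lo,
                "hi": nd.hi,
            }
            for sid, nd in db.stored_nulls.items()
        },
        "feature_table": [
            {"sample_id": fv.sample_id, "r": fv.r.tolist()} for fv in db.feature_table
        ],
        "coefficients": None
        if db.coefficients is None
        else {
            "beta": db.coefficients.beta.tolist(),
            "bin_width": db.coefficients.bin_width,
            "lo": db.coefficients.lo,
            "hi": db.coefficients.hi,
            "loss": db.coefficients.loss,
            "clip_eps": db.coefficients.clip_eps,
        },
        "coefficients_stale": db.coefficients_stale,
    }
    Path(path).write_text(json.dumps(payload))


def load_db(path: str | Path) -> FeatureDatabase:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported feature-database schema version {version!r}")
    for component in ("stored_nulls", "feature_table", "reference_histogram"):
        if component not in payload:
            raise ValueError(f"feature database missing component {component!r}")
    nulls = {
        sid: NullDistribution(
            counts=np.asarray(d["counts"], dtype=float),
            bin_width=d["bin_width"],
            lo=d["lo"],
            hi=d["hi"],
        )
        for sid, d in payload["stored_nulls"].items()
    }
    features = [
        FeatureVector(sample_id=d["sample_id"], r=np.asarray(d["r"], dtype=float))
        for d in payload["feature_table"]
    ]
    ref = payload["reference_histogram"]
    coeffs = payload.get("coefficients")
    return FeatureDatabase(
        protein_db_path=payload["protein_db_path"],
        stored_nulls=nulls,
        feature_table=features,
        reference_sample_id=payload["reference_sample_id"],
        reference_histogram=ScoreHistogram(
            probs=np.asarray(ref["probs"], dtype=float), lo=ref["lo"], hi=ref["hi"]
        ),
        coefficients=None
        if coeffs is None
        else CoefficientTable(
            beta=np.asarray(coeffs["beta"], dtype=float),
            bin_width=coeffs["bin_width"],
            lo=coeffs["lo"],
            hi=coeffs["hi"],
            loss=coeffs["loss"],
            clip_eps=coeffs["clip_eps"],
        ),
        coefficients_stale=payload.get("coefficients_stale", False),
        config=DbConfig(**payload.get("config", {})),
    )


def match_sample(db: FeatureDatabase, r0: FeatureVector) -> str | None:
    """Most similar stored sample, or None if none is similar enough."""
    if not db.feature_table:
        raise ValueError("feature database holds no samples")
    if r0.J >= 2:
        best_id, best_corr = None, -np.inf
        for fv in db.feature_table:
            corr = float(np.corrcoef(r0.r, fv.r)[0, 1])
            if corr > best_corr:
                best_id, best_corr = fv.sample_id, corr
        return best_id if best_corr > db.config.corr_threshold else None
    best_id, best_dist = None, np.inf
    for fv in db.feature_table:
        dist = abs(float(r0.r[0]) - float(fv.r[0]))
        if dist < best_dist:
            best_id, best_dist = fv.sample_id, dist
    return best_id if best_dist <= db.config.feature_tolerance else None


def resolve_null(
    db: FeatureDatabase, sample: SampleScores
) -> tuple[NullDistribution, str]:
    """Reuse a similar stored null or infer one from the coefficient table.

    Returns (null, provenance) with provenance "matched:<sample_id>" or
    "inferred". The matched branch returns the stored null object
    unchanged; the inferred branch never writes to the database.
    """
    hist = score_histogram(sample, n_bins=db.config.n_feature_bins)
    r0 = FeatureVector(
        sample_id=sample.sample_id,
        r=np.array([kl_divergence(hist, db.reference_histogram, eps=db.config.kl_eps)]),
    )
    matched = match_sample(db, r0)
    if matched is not None:
        return db.stored_nulls[matched], f"matched:{matched}"
    if db.coefficients is None:
        raise ValueError("no similar stored sample and no coefficient table to infer from")
    if db.coefficients_stale:
        raise ValueError("coefficient table is stale; refit before inferring")
    return infer_null(db.coefficients, r0), "inferred"


def add_sample(
    db: FeatureDatabase,
    sample_id: str,
    features: FeatureVector,
    null: NullDistribution,
) -> FeatureDatabase:
    """Return a new database with the sample appended.

    The coefficient table is marked stale until refit.
    """
    if sample_id in db.stored_nulls:
        raise ValueError(f"sample {sample_id!r} already stored")
    if db.stored_nulls:
        existing = next(iter(db.stored_nulls.values()))
        if null.K != existing.K or null.bin_width != existing.bin_width:
            raise ValueError("new null's bin structure does not match the database")
    nulls = dict(db.stored_nulls)
    nulls[sample_id] = null
    table = list(db.feature_table) + [
        FeatureVector(sample_id=sample_id, r=features.r)
    ]
    return FeatureDatabase(
        protein_db_path=db.protein_db_path,
        stored_nulls=nulls,
        feature_table=table,
        reference_sample_id=db.reference_sample_id,
        reference_histogram=db.reference_histogram,
        coefficients=db.coefficients,
        coefficients_stale=db.coefficients is not None,
        config=db.config,
    )
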