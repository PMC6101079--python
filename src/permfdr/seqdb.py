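"""Protein sequence databases and target-decoy construction.

Decoy databases are built by shuffling each target sequence uniformly at
random (Fisher-Yates over the whole sequence) and appending the shuffled
copies to the targets, giving a 1:1 concatenated target-decoy database.
Decoys are labelled by a case-sensitive accession prefix (default
``DECOY_``). Repeated shuffles — the permutation repeats that feed the
empirical null — are produced by re-running with different seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_DECOY_PREFIX = "DECOY_"


@dataclass
class ProteinRecord:
    """A single protein database entry.

    The sequence is an uppercase amino-acid string; the 20 standard
    residues plus the ambiguity letters B, Z, X, U, O are tolerated.
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.accession!r}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA protein database into a list of records.

    Sequence lines are concatenated, whitespace stripped and letters
    uppercased. Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` for an empty sequence or a duplicate accession.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(accession=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` characters."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Return a uniformly random permutation of the residues of ``sequence``.

    Length and residue multiset are conserved; the draw is deterministic
    given the state of ``rng``.
    """
    if not sequence:
        raise ValueError("cannot shuffle an empty sequence")
    chars = np.array(list(sequence))
    return "".join(rng.permutation(chars))


def build_target_decoy_db(
    records: list[ProteinRecord],
    seed: int,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> list[ProteinRecord]:
    """Build a 1:1 concatenated target-decoy database.

    Returns the targets unchanged followed by one shuffled decoy per
    target; each decoy accession is ``decoy_prefix + target accession``.
    A target accession already carrying the prefix is an error (the
    labelling would be ambiguous).
    """
    if not decoy_prefix:
        raise ValueError("decoy_prefix must be non-empty")
    for r in records:
        if r.accession.startswith(decoy_prefix):
            raise ValueError(
                f"target accession {r.accession!r} already starts with decoy prefix {decoy_prefix!r}"
            )
    rng = np.random.default_rng(seed)
    decoys = [
        ProteinRecord(
            accession=decoy_prefix + r.accession,
            sequence=shuffle_sequence(r.sequence, rng),
            description=f"shuffled decoy of {r.accession}",
        )
        for r in records
    ]
    return list(records) + decoys


def is_decoy(accession: str, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> bool:
    """True iff ``accession`` starts with the (case-sensitive) decoy prefix."""
    return accession.startswith(decoy_prefix)
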