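"""Domain types and file I/O for the 14-3-3 docking-site ranker.

The unit of prediction is a candidate site: one Ser or Thr residue on a
protein together with the number of independent mass-spectrometry studies
that observed it phosphorylated.  All coordinates are 1-based, matching the
"S502"/"T2467" residue-naming convention used in the 14-3-3 literature.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Letters accepted in input sequences.  X (unknown residue) is tolerated but
#: scored as background by the sequence model.
VALID_LETTERS = frozenset(AMINO_ACIDS + "X")

#: Column layout of predictions.tsv, in writing order.
PREDICTION_COLUMNS = [
    "protein_id", "position", "residue", "n_obs",
    "ptm_score", "disorder", "ann", "svm", "pssm",
    "total_score", "total_rank",
    "ptmdis_score", "ptmdis_rank",
    "seq_score", "seq_rank",
    "adapted_score", "adapted_rank",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an opaque identifier."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise DataError("empty protein_id")
        if not self.sequence:
            raise DataError(f"empty sequence for {self.protein_id}")
        bad = set(self.sequence) - VALID_LETTERS
        if bad:
            raise DataError(
                f"non-canonical letters {sorted(bad)} in {self.protein_id}"
            )

    @property
    def has_unknown_residues(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateSite:
    """One Ser/Thr residue with its MS observation count (0 = never seen)."""

    protein_id: str
    position: int  # 1-based
    residue: str  # "S" or "T"
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T"):
            raise DataError(
                f"candidate residue must be S or T, got {self.residue!r} "
                f"at {self.protein_id}:{self.position}"
            )
        if self.position < 1:
            raise DataError(f"position must be 1-based, got {self.position}")
        if self.n_obs < 0:
            raise DataError(f"negative n_obs at {self.protein_id}:{self.position}")


class ObservationTable:
    """Phosphosite observation counts indexed by (protein_id, position).

    Stores one positive count per observed phosphosite and the per-protein
    total over all observed sites, which is the denominator of the PTM
    observation-frequency score.
    """

    def __init__(self) -> None:
        self._counts: dict[tuple[str, int], int] = {}
        self._residues: dict[tuple[str, int], str] = {}
        self._totals: dict[str, int] = {}

    @classmethod
    def from_records(
        cls, records: list[tuple[str, int, str, int]]
    ) -> "ObservationTable":
        """Build from (protein_id, position, residue, n_obs) rows."""
        table = cls()
        for protein_id, position, residue, n_obs in records:
            table.add(protein_id, int(position), residue, int(n_obs))
        return table

    def add(self, protein_id: str, position: int, residue: str, n_obs: int) -> None:
        key = (protein_id, position)
        if key in self._counts:
            raise DataError(f"duplicate observation row {protein_id}:{position}")
        if n_obs < 1:
            raise DataError(
                f"n_obs must be >= 1 for stored entries, got {n_obs} "
                f"at {protein_id}:{position}"
            )
        if residue not in ("S", "T"):
            raise DataError(
                f"observed residue must be S or T, got {residue!r} "
                f"at {protein_id}:{position}"
            )
        self._counts[key] = n_obs
        self._residues[key] = residue
        self._totals[protein_id] = self._totals.get(protein_id, 0) + n_obs

    def n_obs(self, protein_id: str, position: int) -> int:
        return self._counts.get((protein_id, position), 0)

    def residue(self, protein_id: str, position: int) -> str | None:
        return self._residues.get((protein_id, position))

    def total_obs(self, protein_id: str) -> int:
        return self._totals.get(protein_id, 0)

    def entries(self) -> list[tuple[str, int, str, int]]:
        return sorted(
            (pid, pos, self._residues[(pid, pos)], n)
            for (pid, pos), n in self._counts.items()
        )

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._counts


@dataclass(frozen=True)
class LabeledSite:
    """A phosphosite with its docking label (1 = validated 14-3-3 docking)."""

    protein_id: str
    position: int
    label: int
    noncanonical: bool = False

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label}")


@dataclass
class Dataset:
    """All inputs for one run: sequences, counts, labels, optional scores.

    ``disorder`` maps protein_id to a dense per-residue score array (from an
    external predictor such as IUPred2A); ``seqscores`` maps
    (protein_id, position) to externally computed (ann, svm, pssm) triples.
    Either may be None, in which case the built-in scorers are used.
    """

    proteins: dict[str, ProteinRecord]
    observations: ObservationTable
    labels: list[LabeledSite] = field(default_factory=list)
    disorder: dict[str, np.ndarray] | None = None
    seqscores: dict[tuple[str, int], tuple[float, float, float]] | None = None

    def validate(self) -> None:
        """Cross-check labels and observations against the sequences."""
        seen: set[tuple[str, int]] = set()
        for site in self.labels:
            key = (site.protein_id, site.position)
            if key in seen:
                raise DataError(f"duplicate labeled site {key}")
            seen.add(key)
            protein = self.proteins.get(site.protein_id)
            if protein is None:
                raise DataError(f"labeled site on unknown protein {site.protein_id}")
            if not 1 <= site.position <= len(protein):
                raise DataError(
                    f"labeled position {site.position} outside "
                    f"{site.protein_id} (length {len(protein)})"
                )
            if protein.sequence[site.position - 1] not in ("S", "T"):
                raise DataError(
                    f"labeled site {site.protein_id}:{site.position} is "
                    f"{protein.sequence[site.position - 1]!r}, not S/T"
                )
        for pid, pos, residue, _ in self.observations.entries():
            protein = self.proteins.get(pid)
            if protein is None:
                raise DataError(f"observation on unknown protein {pid}")
            if not 1 <= pos <= len(protein):
                raise DataError(f"observation position {pos} outside {pid}")
            if protein.sequence[pos - 1] != residue:
                raise DataError(
                    f"residue mismatch at {pid}:{pos}: table says {residue}, "
                    f"sequence has {protein.sequence[pos - 1]}"
                )

    def positives(self) -> list[LabeledSite]:
        return [s for s in self.labels if s.label == 1]

    def client_protein_ids(self) -> list[str]:
        """Proteins carrying at least one validated docking site, sorted."""
        return sorted({s.protein_id for s in self.labels if s.label == 1})

    def digest(self) -> str:
        """Stable content hash over proteins and observations.

        Labels are deliberately excluded: the digest identifies the inputs
        features are computed from, so a model trained on a dataset can be
        used to score the same sequences/observations without labels and
        still match.
        """
        h = hashlib.sha256()
        for pid in sorted(self.proteins):
            h.update(f"{pid}\t{self.proteins[pid].sequence}\n".encode())
        for row in self.observations.entries():
            h.update(("\t".join(map(str, row)) + "\n").encode())
        return h.hexdigest()[:16]


def read_fasta(path) -> dict[str, ProteinRecord]:
    """Read a multi-record FASTA file into ProteinRecords.

    Sequences are uppercased and whitespace-stripped; a duplicate identifier
    or an empty sequence is a hard error.
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in records:
            raise DataError(f"duplicate id {pid} in {path}")
        seq = str(rec.seq).upper().replace(" ", "").replace("*", "")
        records[pid] = ProteinRecord(pid, seq)
    return records


def write_fasta(proteins: dict[str, ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            seq = proteins[pid].sequence
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_observation_table(path) -> ObservationTable:
    """Read a PhosphoSitePlus-style observation-count TSV.

    Expected header: ``protein_id  position  residue  n_obs``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "position", "residue", "n_obs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"observation table {path} missing columns {missing}")
    if len(df) and not (df["position"] == df["position"].astype(int)).all():
        raise DataError("non-integer position in observation table")
    return ObservationTable.from_records(
        list(
            zip(
                df["protein_id"],
                df["position"].astype(int),
                df["residue"],
                df["n_obs"].astype(int),
            )
        )
    )


def write_observation_table(table: ObservationTable, path) -> None:
    df = pd.DataFrame(
        table.entries(), columns=["protein_id", "position", "residue", "n_obs"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> list[LabeledSite]:
    """Read a labeled-site TSV: ``protein_id  position  label`` (+optional
    ``noncanonical`` 0/1 column)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "position", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"label table {path} missing columns {missing}")
    has_nc = "noncanonical" in df.columns
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            LabeledSite(
                row.protein_id,
                int(row.position),
                int(row.label),
                noncanonical=bool(int(row.noncanonical)) if has_nc else False,
            )
        )
    keys = [(s.protein_id, s.position) for s in sites]
    if len(keys) != len(set(keys)):
        raise DataError(f"duplicate labeled site in {path}")
    return sites


def write_labels(labels: list[LabeledSite], path) -> None:
    df = pd.DataFrame(
        [
            (s.protein_id, s.position, s.label, int(s.noncanonical))
            for s in labels
        ],
        columns=["protein_id", "position", "label", "noncanonical"],
    )
    df.to_csv(path, sep="\t", index=False)


def enumerate_candidates(
    protein: ProteinRecord, observations: ObservationTable
) -> list[CandidateSite]:
    """All Ser/Thr residues of a protein, ascending position, with counts.

    The prediction universe is every S/T, not only observed phosphosites;
    sites absent from the observation table get n_obs = 0.  An observation
    entry whose stored residue disagrees with the sequence is a coordinate
    mismatch and a hard error.
    """
    sites = []
    for idx, letter in enumerate(protein.sequence, start=1):
        if letter in ("S", "T"):
            stored = observations.residue(protein.protein_id, idx)
            if stored is not None and stored != letter:
                raise DataError(
                    f"residue mismatch at {protein.protein_id}:{idx}: "
                    f"table says {stored}, sequence has {letter}"
                )
            sites.append(
                CandidateSite(
                    protein.protein_id,
                    idx,
                    letter,
                    observations.n_obs(protein.protein_id, idx),
                )
            )
    return sites


def write_predictions(predictions: pd.DataFrame, path) -> None:
    """Write the ranked-prediction table, sorted by protein then total_rank."""
    missing = [c for c in PREDICTION_COLUMNS if c not in predictions.columns]
    if missing:
        raise DataError(f"predictions missing columns {missing}")
    out = predictions[PREDICTION_COLUMNS].sort_values(
        ["protein_id", "total_rank"], kind="stable"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str})
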