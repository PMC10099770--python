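"""The five model inputs per candidate site.

A site is described by three consensus-sequence scores (ANN / SVM / PSSM,
either ingested from an external predictor or served by the built-in
position-specific scoring matrix), a per-residue intrinsic-disorder score,
and the PTM score: the site's MS observation count normalized by the total
observation count of all phosphorylations on that protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .core_data import (
    AMINO_ACIDS,
    CandidateSite,
    DataError,
    Dataset,
    LabeledSite,
    ObservationTable,
    ProteinRecord,
)

#: Window offsets relative to the phosphosite (0 excluded).  The default
#: -5..+4 covers the mode I determinants (-3 Arg, +2 Pro) and the mode II
#: determinants (-4 Arg, -2 Phe/Tyr).
DEFAULT_OFFSETS: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4)

#: Sentinel letter for window positions that fall outside the sequence (or
#: on an X); scored as background, i.e. log-odds 0.
SENTINEL = "-"

_LETTER_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_SENTINEL_INDEX = len(AMINO_ACIDS)  # 20

# Feature column names, in model order.
FEATURE_COLUMNS = ["ann", "svm", "pssm", "disorder", "ptm_score"]
FLAG_COLUMNS = ["missing_ptm", "builtin_seq", "builtin_disorder"]


def uniform_background() -> dict[str, float]:
    return {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}


def compute_ptm_score(site: CandidateSite, table: ObservationTable) -> float:
    """Observation count of the site over the protein's total count.

    Returns 0 when the site is unobserved or the protein has no observed
    phosphosites at all; callers flag that case as a missing PTM score.
    """
    total = table.total_obs(site.protein_id)
    if total == 0 or site.n_obs == 0:
        return 0.0
    return site.n_obs / total


def extract_window(
    sequence: str, position: int, offsets: tuple[int, ...] = DEFAULT_OFFSETS
) -> str:
    """Letters at position+offset for each offset (1-based position).

    Out-of-range offsets and unknown residues (X) yield the sentinel, which
    the PSSM scores as background.
    """
    letters = []
    for off in offsets:
        idx = position - 1 + off
        if 0 <= idx < len(sequence) and sequence[idx] != "X":
            letters.append(sequence[idx])
        else:
            letters.append(SENTINEL)
    return "".join(letters)


def encode_windows(windows: list[str]) -> np.ndarray:
    """Integer-encode windows (sentinel -> 20) for vectorized PSSM scoring."""
    out = np.empty((len(windows), len(windows[0]) if windows else 0), dtype=np.int8)
    for i, win in enumerate(windows):
        for j, letter in enumerate(win):
            out[i, j] = _LETTER_INDEX.get(letter, _SENTINEL_INDEX)
    return out


@dataclass
class PSSMModel:
    """Additive log-odds model of residue preferences around a phosphosite.

    ``table`` has one row per window offset and one column per amino acid
    plus a trailing all-zero sentinel column.  Scores are sums of log2
    odds over the window; a window drawn from background scores 0 in
    expectation under the pseudocount-free limit.
    """

    offsets: tuple[int, ...]
    table: np.ndarray  # shape (len(offsets), 21)
    background: dict[str, float]
    pseudocount: float

    def cell(self, offset: int, letter: str) -> float:
        return float(
            self.table[self.offsets.index(offset), _LETTER_INDEX[letter]]
        )

    def score_window(self, window: str) -> float:
        codes = encode_windows([window])[0]
        return float(self.table[np.arange(len(self.offsets)), codes].sum())

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        """Score many pre-encoded windows at once."""
        return self.table[np.arange(len(self.offsets)), codes].sum(axis=1)


def build_pssm(
    positive_windows: list[str],
    background: dict[str, float] | None = None,
    pseudocount: float = 1.0,
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
) -> PSSMModel:
    """Fit a log-odds matrix from aligned positive windows.

    cell(offset, a) = log2(((count + pc*bg(a)) / (N + pc)) / bg(a)).
    Sentinel positions in the input windows are ignored in the counts;
    the sentinel column of the output is identically zero.
    """
    if not positive_windows:
        raise DataError("cannot build PSSM from zero positive windows")
    widths = {len(w) for w in positive_windows}
    if widths != {len(offsets)}:
        raise DataError(
            f"window widths {sorted(widths)} do not match offsets "
            f"(expected {len(offsets)})"
        )
    background = background or uniform_background()
    if any(background.get(a, 0.0) <= 0 for a in AMINO_ACIDS):
        raise DataError("background must be strictly positive for all letters")
    z = sum(background[a] for a in AMINO_ACIDS)
    bg = np.array([background[a] / z for a in AMINO_ACIDS])

    n_off = len(offsets)
    counts = np.zeros((n_off, len(AMINO_ACIDS)))
    n_eff = np.zeros(n_off)  # sentinel positions do not count as evidence
    codes = encode_windows(positive_windows)
    for j in range(n_off):
        col = codes[:, j]
        real = col[col != _SENTINEL_INDEX]
        n_eff[j] = len(real)
        np.add.at(counts[j], real, 1.0)

    table = np.zeros((n_off, len(AMINO_ACIDS) + 1))
    for j in range(n_off):
        denom = n_eff[j] + pseudocount
        if denom == 0:  # all-sentinel column: leave at background
            continue
        freq = (counts[j] + pseudocount * bg) / denom
        table[j, : len(AMINO_ACIDS)] = np.log2(freq / bg)
    return PSSMModel(
        tuple(offsets), table, {a: float(b) for a, b in zip(AMINO_ACIDS, bg)},
        pseudocount,
    )


def score_pssm(model: PSSMModel, sequence: str, position: int) -> float:
    """Sum of log-odds cells over the window around ``position`` (1-based)."""
    return model.score_window(extract_window(sequence, position, model.offsets))


def build_pssm_from_labels(
    dataset: Dataset,
    positives: list[LabeledSite] | None = None,
    background: dict[str, float] | None = None,
    pseudocount: float = 1.0,
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
) -> PSSMModel:
    """Fit the built-in PSSM from the windows around validated docking sites."""
    positives = dataset.positives() if positives is None else positives
    windows = []
    for site in positives:
        if site.label != 1:
            continue
        protein = dataset.proteins[site.protein_id]
        windows.append(extract_window(protein.sequence, site.position, offsets))
    return build_pssm(windows, background, pseudocount, offsets)


# --- intrinsic disorder -----------------------------------------------------

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


def builtin_disorder(
    sequence: str, half_window: int = 25, logistic_k: float = 10.0
) -> np.ndarray:
    """Per-residue disorder propensity from windowed hydropathy and charge.

    Uses the FoldIndex closed form: over a clipped window of
    ``2*half_window + 1`` residues the mean Kyte-Doolittle hydropathy <H>
    (rescaled to [0, 1]) and the absolute mean net charge <q> combine as
    foldindex = 2.785*<H> - |<q>| - 1.151; negative values indicate
    disorder.  The fold index is squashed through a logistic so the output
    lives on [0, 1] with disorder > 0.5 exactly when foldindex < 0.

    This is a deliberately simple composition-based stand-in used when no
    external disorder table is supplied; it captures the low-hydropathy /
    high-charge signature of disordered regions but none of the
    energy-based context an external predictor models.
    """
    n = len(sequence)
    hydro = np.array(
        [(KYTE_DOOLITTLE.get(a, 0.0) + 4.5) / 9.0 for a in sequence]
    )
    charge = np.array([_CHARGE.get(a, 0.0) for a in sequence])
    # cumulative sums for O(n) clipped-window means
    ch = np.concatenate([[0.0], np.cumsum(hydro)])
    cq = np.concatenate([[0.0], np.cumsum(charge)])
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        width = hi - lo
        mean_h = (ch[hi] - ch[lo]) / width
        mean_q = (cq[hi] - cq[lo]) / width
        foldindex = 2.785 * mean_h - abs(mean_q) - 1.151
        out[i] = 1.0 / (1.0 + np.exp(logistic_k * foldindex))
    return out


def ingest_disorder(path, proteins: dict[str, ProteinRecord]) -> dict[str, np.ndarray]:
    """Read per-residue disorder scores: TSV ``protein_id  position  score``.

    Profiles must be complete (one row per residue) and scores in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "position", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"disorder table {path} missing columns {missing}")
    profiles: dict[str, np.ndarray] = {}
    for pid, group in df.groupby("protein_id"):
        protein = proteins.get(pid)
        if protein is None:
            raise DataError(f"disorder rows for unknown protein {pid}")
        scores = group["score"].to_numpy(dtype=float)
        positions = group["position"].to_numpy(dtype=int)
        if (scores < 0).any() or (scores > 1).any():
            raise DataError(f"disorder score outside [0,1] for {pid}")
        if (positions < 1).any() or (positions > len(protein)).any():
            raise DataError(f"disorder position outside sequence for {pid}")
        if len(set(positions)) != len(positions):
            raise DataError(f"duplicate disorder position for {pid}")
        if len(positions) != len(protein):
            raise DataError(
                f"incomplete profile for {pid}: {len(positions)} of "
                f"{len(protein)} residues"
            )
        profile = np.empty(len(protein))
        profile[positions - 1] = scores
        profiles[pid] = profile
    return profiles


def ingest_sequence_scores(path) -> dict[tuple[str, int], tuple[float, float, float]]:
    """Read external (ann, svm, pssm) score triples per site.

    TSV ``protein_id  position  ann  svm  pssm``.  Sites absent from the
    file are later served by the built-in PSSM (fallback flagged).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "position", "ann", "svm", "pssm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"sequence-score table {path} missing columns {missing}")
    mapping: dict[tuple[str, int], tuple[float, float, float]] = {}
    for row in df.itertuples(index=False):
        key = (row.protein_id, int(row.position))
        if key in mapping:
            raise DataError(f"duplicate sequence-score row {key}")
        mapping[key] = (float(row.ann), float(row.svm), float(row.pssm))
    return mapping


def consensus_rescale(raw_pssm: np.ndarray | float) -> np.ndarray | float:
    """Map a raw log-odds PSSM score onto [0, 1] via a logistic.

    Used so the built-in PSSM can stand behind the same 0.5/0.8 consensus
    cutoffs that external consensus scores use.
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(raw_pssm, dtype=float)))


# --- assembly ---------------------------------------------------------------


def candidate_table(dataset: Dataset) -> pd.DataFrame:
    """Enumerate all candidates with label-independent features attached.

    Returns one row per S/T with protein_id, position, residue, n_obs,
    ptm_score, disorder, the missing/stand-in flags, and the pre-encoded
    PSSM window codes (as an object column), so that fold-specific sequence
    scores can be recomputed cheaply without touching the sequences again.
    """
    from .core_data import enumerate_candidates

    rows = []
    win_codes = []
    for pid in sorted(dataset.proteins):
        protein = dataset.proteins[pid]
        if dataset.disorder is not None:
            # external disorder mandated: every protein must be covered
            if pid not in dataset.disorder:
                raise DataError(f"no disorder profile for {pid}")
            profile = dataset.disorder[pid]
            builtin_dis = False
            if len(profile) != len(protein):
                raise DataError(f"disorder profile length mismatch for {pid}")
        else:
            profile = builtin_disorder(protein.sequence)
            builtin_dis = True
        for site in enumerate_candidates(protein, dataset.observations):
            ptm = compute_ptm_score(site, dataset.observations)
            rows.append(
                {
                    "protein_id": pid,
                    "position": site.position,
                    "residue": site.residue,
                    "n_obs": site.n_obs,
                    "ptm_score": ptm,
                    "disorder": float(profile[site.position - 1]),
                    "missing_ptm": site.n_obs == 0,
                    "builtin_disorder": builtin_dis,
                }
            )
            win_codes.append(
                extract_window(protein.sequence, site.position, DEFAULT_OFFSETS)
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "position", "residue", "n_obs",
            "ptm_score", "disorder", "missing_ptm", "builtin_disorder",
        ],
    )
    df["window"] = win_codes
    return df


def attach_sequence_scores(
    candidates: pd.DataFrame,
    pssm: PSSMModel,
    seqscores: dict[tuple[str, int], tuple[float, float, float]] | None = None,
    codes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fill the ann/svm/pssm columns for a candidate table.

    External triples are used verbatim where present; otherwise the built-in
    PSSM score is replicated into all three slots and flagged — the forest
    sees the same information either way.  ``pssm`` must be fit on training
    positives only when the result feeds a held-out evaluation.
    ``codes`` may carry pre-encoded windows to avoid re-encoding per fold.
    """
    df = candidates.copy()
    if codes is None:
        codes = encode_windows(list(df["window"]))
    builtin = pssm.score_codes(codes) if len(df) else np.zeros(0)
    ann = builtin.copy()
    svm = builtin.copy()
    pss = builtin.copy()
    flags = np.ones(len(df), dtype=bool)
    if seqscores:
        for i, (pid, pos) in enumerate(zip(df["protein_id"], df["position"])):
            triple = seqscores.get((pid, int(pos)))
            if triple is not None:
                ann[i], svm[i], pss[i] = triple
                flags[i] = False
    df["ann"] = ann
    df["svm"] = svm
    df["pssm"] = pss
    df["builtin_seq"] = flags
    return df


def assemble_features(
    dataset: Dataset,
    pssm: PSSMModel | None = None,
    pssm_pseudocount: float = 1.0,
    pssm_offsets: tuple[int, ...] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """Complete feature table for every candidate S/T in the dataset.

    When no PSSM is given, one is fit from the dataset's own validated
    docking sites (only appropriate outside held-out evaluation; the
    evaluation protocols pass fold-specific models instead).
    """
    base = candidate_table(dataset)
    if pssm is None:
        if dataset.seqscores:
            # external scores may fully cover the candidates; a PSSM is still
            # needed for any site absent from the table
            try:
                pssm = build_pssm_from_labels(
                    dataset, pseudocount=pssm_pseudocount, offsets=pssm_offsets
                )
            except DataError:
                pssm = PSSMModel(
                    tuple(pssm_offsets),
                    np.zeros((len(pssm_offsets), len(AMINO_ACIDS) + 1)),
                    uniform_background(),
                    pssm_pseudocount,
                )
        else:
            pssm = build_pssm_from_labels(
                dataset, pseudocount=pssm_pseudocount, offsets=pssm_offsets
            )
    return attach_sequence_scores(base, pssm, dataset.seqscores)
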