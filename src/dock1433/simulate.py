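"""Seeded synthetic phosphoproteome datasets.

The generator emulates the statistical structure the ranker assumes about
real 14-3-3 client proteins:

* docking sites sit in consensus-like sequence context — an Arg at -3 and
  a Pro at +2 (mode I) or a Phe/Tyr at -2 (mode II), each emitted with a
  configurable probability rather than deterministically, since the real
  consensus is loose;
* the local composition around a docking site is biased toward
  disorder-promoting residues, so the windowed-composition disorder score
  is elevated there;
* docking phosphosites are observed in far more MS studies than decoy
  phosphosites (negative-binomial counts with a higher mean), while most
  decoy Ser/Thr are never observed at all.

Each of the three signal channels has an independent switch; with a switch
off, the corresponding signal is exchangeable between docking and decoy
sites, which is what the null-calibration checks rely on.  Every protein's
content is derived from its own sub-seed, so records are independent and
the whole dataset is byte-reproducible from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .core_data import (
    AMINO_ACIDS,
    DataError,
    Dataset,
    LabeledSite,
    ObservationTable,
    ProteinRecord,
    write_fasta,
    write_labels,
    write_observation_table,
)
from .model import derive_seed

#: Residues favouring intrinsic disorder (low hydropathy and/or charge).
#: Ser is deliberately excluded so composition enrichment never changes the
#: candidate Ser/Thr universe of a protein.
DISORDER_POOL = "EKPQGD"

_NON_ST = "".join(a for a in AMINO_ACIDS if a not in "ST")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a moderately hard but clearly learnable problem:
    100 client proteins of realistic length with 60 candidate Ser/Thr each,
    mostly one (sometimes two) docking sites, a loose mode I/II motif, a
    strong but overlapping observation-count shift (negative-binomial means
    20 vs 3 at dispersion 1, decoys observed at all only 30% of the time),
    and local disorder-promoting composition around docking sites.
    """

    seed: int
    n_proteins: int = 100
    length_range: tuple[int, int] = (500, 700)
    n_st: int = 60  # candidate S/T residues planted per protein
    p_sites: tuple[float, float, float] = (0.0, 0.8, 0.2)  # 0/1/2 docking sites
    # motif emission probabilities
    p_r_minus3: float = 0.7
    p_p_plus2: float = 0.45
    p_fy_minus2: float = 0.25
    # disorder-composition enrichment around docking sites; the bias is a
    # ring adjacent to the site, outside the consensus window (|offset| > 5),
    # so the disorder and sequence-motif channels stay independent
    p_pool: float = 0.9
    disorder_halfwidth: int = 20
    motif_exclusion: int = 5
    # observation model
    mean_true: float = 20.0
    mean_decoy: float = 3.0
    dispersion: float = 1.0
    p_obs_true: float = 0.9
    p_obs_decoy: float = 0.3
    # signal switches
    motif_on: bool = True
    disorder_on: bool = True
    ptm_on: bool = True

    def __post_init__(self) -> None:
        probs = [
            *self.p_sites, self.p_r_minus3, self.p_p_plus2, self.p_fy_minus2,
            self.p_pool, self.p_obs_true, self.p_obs_decoy,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise DataError("probabilities must lie in [0, 1]")
        if abs(sum(self.p_sites) - 1.0) > 1e-9:
            raise DataError("p_sites must sum to 1")
        if self.mean_true < self.mean_decoy:
            raise DataError("mean_true must be >= mean_decoy")
        if self.n_proteins < 0:
            raise DataError("n_proteins must be >= 0")
        if self.length_range[0] > self.length_range[1]:
            raise DataError("invalid length_range")
        if self.n_st > self.length_range[0]:
            raise DataError("n_st exceeds minimum protein length")
        max_sites = 2 if self.p_sites[2] > 0 else (1 if self.p_sites[1] > 0 else 0)
        if max_sites > self.n_st:
            raise DataError("more docking sites requested than S/T capacity")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        d["p_sites"] = list(self.p_sites)
        return d


def _n_docking(config: SimulationConfig, index: int) -> int:
    rng = np.random.default_rng(derive_seed(config.seed, "ndock", index))
    return int(rng.choice([0, 1, 2], p=list(config.p_sites)))


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _simulate_protein(
    config: SimulationConfig, index: int, noncanonical_slots: frozenset[int]
) -> tuple[ProteinRecord, list[tuple[int, str, int]], list[LabeledSite]]:
    """One protein: (record, observed (pos, residue, count) rows, labels).

    ``noncanonical_slots`` lists docking-site ordinals (0 or 1) of this
    protein whose motif emission is suppressed.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "protein", index))
    pid = f"SYN{index:04d}"
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))

    st_pos = np.sort(rng.choice(length, size=config.n_st, replace=False))
    letters = rng.choice(list(_NON_ST), size=length)
    letters[st_pos] = rng.choice(["S", "T"], size=config.n_st)
    st_set = set(int(p) for p in st_pos)

    n_dock = _n_docking(config, index)
    dock_pos: list[int] = []
    if n_dock:
        # prefer docking sites separated enough that motifs do not overlap
        for _ in range(200):
            pick = rng.choice(st_pos, size=n_dock, replace=False)
            if n_dock == 1 or abs(int(pick[0]) - int(pick[1])) > 10:
                dock_pos = sorted(int(p) for p in pick)
                break
        else:
            dock_pos = sorted(int(p) for p in rng.choice(st_pos, n_dock, False))

    def plant(pos0: int, letter: str) -> None:
        # never overwrite a candidate S/T: the universe stays fixed
        if 0 <= pos0 < length and pos0 not in st_set:
            letters[pos0] = letter

    labels = []
    for ordinal, p0 in enumerate(dock_pos):
        noncanonical = ordinal in noncanonical_slots
        if config.disorder_on:
            lo = max(0, p0 - config.disorder_halfwidth)
            hi = min(length, p0 + config.disorder_halfwidth + 1)
            for j in range(lo, hi):
                if abs(j - p0) <= config.motif_exclusion:
                    continue  # keep the consensus window at background
                if j not in st_set and rng.random() < config.p_pool:
                    letters[j] = rng.choice(list(DISORDER_POOL))
        if config.motif_on and not noncanonical:
            if rng.random() < config.p_r_minus3:
                plant(p0 - 3, "R")
            if rng.random() < config.p_p_plus2:
                plant(p0 + 2, "P")
            if rng.random() < config.p_fy_minus2:
                plant(p0 - 2, str(rng.choice(["F", "Y"])))
        labels.append(LabeledSite(pid, p0 + 1, 1, noncanonical=noncanonical))

    sequence = "".join(letters)
    dock_set = set(dock_pos)
    observations = []
    for p0 in st_pos:
        p0 = int(p0)
        is_true = p0 in dock_set
        if is_true and config.ptm_on:
            observed = rng.random() < config.p_obs_true
            mean = config.mean_true
        else:
            observed = rng.random() < config.p_obs_decoy
            mean = config.mean_decoy
        if observed:
            count = max(1, _negbin(rng, mean, config.dispersion))
            observations.append((p0 + 1, sequence[p0], count))
    return ProteinRecord(pid, sequence), observations, labels


def _simulate(
    config: SimulationConfig, noncanonical: dict[int, frozenset[int]]
) -> Dataset:
    proteins: dict[str, ProteinRecord] = {}
    table = ObservationTable()
    labels: list[LabeledSite] = []
    for i in range(config.n_proteins):
        record, obs, site_labels = _simulate_protein(
            config, i, noncanonical.get(i, frozenset())
        )
        proteins[record.protein_id] = record
        for pos, residue, count in obs:
            table.add(record.protein_id, pos, residue, count)
        labels.extend(site_labels)
    dataset = Dataset(proteins, table, labels)
    dataset.validate()
    return dataset


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Generate a fully labeled synthetic dataset from the config."""
    return _simulate(config, {})


def simulate_noncanonical(config: SimulationConfig, fraction: float) -> Dataset:
    """As ``simulate_dataset`` but suppress motif emission for a fraction of
    docking sites (exactly round(fraction * n_sites) of them, chosen under
    the seed); PTM and disorder signals are retained and the affected sites
    carry the noncanonical flag in the labels."""
    if not 0 <= fraction <= 1:
        raise DataError("noncanonical fraction must lie in [0, 1]")
    slots = [
        (i, j)
        for i in range(config.n_proteins)
        for j in range(_n_docking(config, i))
    ]
    n_pick = int(round(fraction * len(slots)))
    rng = np.random.default_rng(derive_seed(config.seed, "noncanonical-pick"))
    picked_idx = rng.choice(len(slots), size=n_pick, replace=False) if n_pick else []
    by_protein: dict[int, set[int]] = {}
    for k in picked_idx:
        i, j = slots[int(k)]
        by_protein.setdefault(i, set()).add(j)
    return _simulate(
        config, {i: frozenset(v) for i, v in by_protein.items()}
    )


def write_simulated(dataset: Dataset, config: SimulationConfig, outdir) -> None:
    """Write FASTA / observations.tsv / labels.tsv / truth.json for a run."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(dataset.proteins, os.path.join(outdir, "proteins.fasta"))
    write_observation_table(
        dataset.observations, os.path.join(outdir, "observations.tsv")
    )
    write_labels(dataset.labels, os.path.join(outdir, "labels.tsv"))
    truth = {
        "config": config.to_dict(),
        "digest": dataset.digest(),
        "sites": [
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "label": s.label,
                "noncanonical": s.noncanonical,
            }
            for s in dataset.labels
        ],
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
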