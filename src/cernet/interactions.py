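"""miRNA-target interaction records: loading, energy filtering, seed matching.

Interaction tables are the parsed output shape of an energy-aware target
predictor (miRanda-like): one row per (miRNA, target) with an alignment
score and a binding free energy in kcal/mol.  More negative energy means
stronger predicted binding, so the conventional reliability filter keeps
records with energy at or below a cutoff (default -20 kcal/mol).

A seed-match predictor is included for fully synthetic runs where no real
predictor output exists: it reports a hit when the reverse complement of the
miRNA seed (positions 2-8, the 7mer-m8 site) occurs in the target.  It is a
deliberately simple stand-in, not a reimplementation of any alignment or
thermodynamic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetInteraction",
    "InteractionSet",
    "load_interactions",
    "predict_targets_seed_match",
    "COLUMNS",
]

COLUMNS = ["mirna_id", "target_id", "target_class", "score", "energy_kcal_mol"]
_REQUIRED = ["mirna_id", "target_id", "target_class"]
_CLASSES = {"mRNA", "circRNA"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InteractionFormatError(ValueError):
    """Raised when an interaction table is structurally invalid."""


@dataclass(frozen=True)
class TargetInteraction:
    mirna_id: str
    target_id: str
    target_class: str
    score: float | None = None
    energy: float | None = None


@dataclass
class InteractionSet:
    """De-duplicated collection of miRNA-target records.

    ``records`` is a DataFrame with columns mirna_id, target_id,
    target_class, score, energy_kcal_mol; (mirna_id, target_id) is unique
    and target_class is consistent per target id.
    """

    records: pd.DataFrame
    n_missing_energy: int = 0

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise InteractionFormatError(f"missing required columns: {missing}")
        for c in ("score", "energy_kcal_mol"):
            if c not in df.columns:
                df[c] = float("nan")
        bad = set(df["target_class"]) - _CLASSES
        if bad:
            raise InteractionFormatError(f"invalid target_class values: {sorted(bad)}")
        if df.duplicated(["mirna_id", "target_id"]).any():
            raise InteractionFormatError("duplicate (mirna_id, target_id) keys")
        per_target = df.groupby("target_id")["target_class"].nunique()
        inconsistent = per_target[per_target > 1].index.tolist()
        if inconsistent:
            raise InteractionFormatError(
                f"inconsistent target_class for targets: {inconsistent}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def mirnas(self) -> set[str]:
        return set(self.records["mirna_id"])

    def targets(self, target_class: str | None = None) -> set[str]:
        df = self.records
        if target_class is not None:
            df = df[df["target_class"] == target_class]
        return set(df["target_id"])

    def partners_of_mirna(self, mirna_id: str) -> set[str]:
        df = self.records
        return set(df.loc[df["mirna_id"] == mirna_id, "target_id"])

    def to_tsv(self, path) -> None:
        self.records[COLUMNS].to_csv(path, sep="\t", index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionSet):
            return NotImplemented
        a = self.records[COLUMNS].sort_values(["mirna_id", "target_id"]).reset_index(drop=True)
        b = other.records[COLUMNS].sort_values(["mirna_id", "target_id"]).reset_index(drop=True)
        return a.equals(b)


def _dedupe_best_energy(df: pd.DataFrame) -> pd.DataFrame:
    # keep the strongest (lowest) energy per (mirna, target); rows without an
    # energy lose to any row that has one
    key = df["energy_kcal_mol"].fillna(float("inf"))
    order = df.assign(_k=key).sort_values(
        ["mirna_id", "target_id", "_k"], kind="mergesort"
    )
    return order.drop_duplicates(["mirna_id", "target_id"], keep="first").drop(
        columns="_k"
    )


def load_interactions(path, energy_cutoff: float = -20.0) -> InteractionSet:
    """Read an interaction TSV and apply the binding-energy filter.

    Records with energy above ``energy_cutoff`` (weaker binding) are removed;
    records with no energy value are kept and counted in
    ``n_missing_energy``.  Duplicate (miRNA, target) rows collapse to the one
    with the lowest energy.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "target_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise InteractionFormatError(
            f"{path}: missing required columns: {missing}"
        )
    for c in ("score", "energy_kcal_mol"):
        if c not in df.columns:
            df[c] = float("nan")
    n_missing = int(df["energy_kcal_mol"].isna().sum())
    if n_missing:
        logger.warning("%s: %d records lack an energy value; kept", path, n_missing)
    keep = df["energy_kcal_mol"].isna() | (df["energy_kcal_mol"] <= energy_cutoff)
    df = _dedupe_best_energy(df[keep]).reset_index(drop=True)
    return InteractionSet(records=df, n_missing_energy=n_missing)


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_dna(seq: str, seq_id: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError(f"invalid alphabet in sequence {seq_id!r}")
    return s


def predict_targets_seed_match(
    mirna_sequences: dict[str, str],
    target_sequences: dict[str, str],
    target_class: str,
) -> InteractionSet:
    """Seed-match (7mer-m8) target prediction for synthetic sequence sets.

    A hit is the exact occurrence of the reverse complement of miRNA
    positions 2-8 in the target (U and T equivalent).  Each hit gets a
    synthetic energy of -20 minus the number of seed sites, so every emitted
    record survives the default energy filter.
    """
    if target_class not in _CLASSES:
        raise ValueError(f"target_class must be one of {sorted(_CLASSES)}")
    rows = []
    for mid in sorted(mirna_sequences):
        mseq = _as_dna(mirna_sequences[mid], mid)
        if len(mseq) < 8:
            raise ValueError(f"miRNA {mid!r} shorter than 8 nt; no seed region")
        site = _revcomp_dna(mseq[1:8])
        for tid in sorted(target_sequences):
            tseq = _as_dna(target_sequences[tid], tid)
            n_sites = tseq.count(site)
            if n_sites:
                rows.append(
                    {
                        "mirna_id": mid,
                        "target_id": tid,
                        "target_class": target_class,
                        "score": 140.0 + 10.0 * n_sites,
                        "energy_kcal_mol": -20.0 - float(n_sites),
                    }
                )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return InteractionSet(records=df)
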