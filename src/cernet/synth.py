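"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a small two-group RNA-seq design (3 case vs 3
control samples) across three RNA classes, with:

* negative-binomial counts (variance mu + mu^2 * dispersion), baseline
  means log-uniform over a configurable range;
* a planted fraction of differentially expressed features per class at a
  fixed |log2 fold change|, split 50/50 up/down;
* an interaction table in which a configured number of circRNA-mRNA pairs
  each share an exact number of miRNAs (drawn from the planted-DE miRNAs so
  the pairs survive every downstream filter), against a sparse Bernoulli
  background; one planted circRNA carries several pairs and acts as the
  ground-truth hub;
* synthetic binding energies in [-35, -20] kcal/mol for genuine records and
  a configurable fraction of weak-energy decoys that the -20 kcal/mol
  filter must remove;
* a GMT gene-set collection with one term enriched in the planted-DE mRNAs.

Everything derives from a single integer seed; identical (config, seed)
yields bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .interactions import COLUMNS, InteractionSet

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "PlantedPair",
    "generate_counts",
    "generate_interactions",
    "generate_gene_sets",
    "SynthConfigError",
    "SynthConsistencyError",
]

CLASSES = ("mRNA", "miRNA", "circRNA")
HUB_PAIR_FRACTION = 0.4  # share of planted pairs routed through the hub circRNA


class SynthConfigError(ValueError):
    """Invalid generator configuration."""


class SynthConsistencyError(ValueError):
    """Ground truth does not match the configuration it is used with."""


@dataclass(frozen=True)
class SynthConfig:
    n_mrna: int = 200
    n_mirna: int = 30
    n_circ: int = 50
    n_samples_per_group: int = 3
    nb_mean_range: tuple[float, float] = (100.0, 1000.0)
    nb_dispersion: float = 0.05
    frac_de: float | dict = field(
        default_factory=lambda: {"mRNA": 0.3, "miRNA": 0.5, "circRNA": 0.4}
    )
    de_log2fc: float = 2.0
    n_planted_pairs: int = 20
    shared_mirnas_per_planted_pair: int = 5
    background_share_prob: float = 0.01
    decoy_frac: float = 0.1
    seed: int = 0

    def frac_de_of(self, cls: str) -> float:
        if isinstance(self.frac_de, dict):
            return float(self.frac_de[cls])
        return float(self.frac_de)

    def validate(self) -> None:
        for name in ("n_mrna", "n_mirna", "n_circ", "n_samples_per_group"):
            if getattr(self, name) <= 0:
                raise SynthConfigError(f"{name} must be positive")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise SynthConfigError("nb_mean_range must be positive (low <= high)")
        if self.nb_dispersion <= 0:
            raise SynthConfigError("nb_dispersion must be positive")
        for cls in CLASSES:
            f = self.frac_de_of(cls)
            if not 0 <= f <= 1:
                raise SynthConfigError(f"frac_de[{cls}] must lie in [0, 1]")
        if self.de_log2fc <= 0:
            raise SynthConfigError("de_log2fc must be positive")
        if self.n_planted_pairs < 0 or self.shared_mirnas_per_planted_pair < 0:
            raise SynthConfigError("pair counts must be non-negative")
        if self.shared_mirnas_per_planted_pair > self.n_mirna:
            raise SynthConfigError("shared miRNAs per pair exceed the miRNA pool")
        if not 0 <= self.background_share_prob <= 1:
            raise SynthConfigError("background_share_prob must be a probability")
        if not 0 <= self.decoy_frac <= 1:
            raise SynthConfigError("decoy_frac must lie in [0, 1]")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PlantedPair:
    circ_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]


@dataclass
class GroundTruth:
    """Planted signal: DE features per class (id -> UP/DOWN), planted
    competing pairs with their exact shared-miRNA sets, and the hub."""

    de_features: dict[str, dict[str, str]]
    planted_pairs: list[PlantedPair]
    hub_circ: str | None
    config_fingerprint: str

    def de_ids(self, cls: str) -> set[str]:
        return set(self.de_features[cls])

    def to_json(self, path) -> None:
        payload = {
            "de_features": self.de_features,
            "planted_pairs": [
                {
                    "circ_id": p.circ_id,
                    "mrna_id": p.mrna_id,
                    "shared_mirnas": sorted(p.shared_mirnas),
                }
                for p in self.planted_pairs
            ],
            "hub_circ": self.hub_circ,
            "config_fingerprint": self.config_fingerprint,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        pairs = [
            PlantedPair(d["circ_id"], d["mrna_id"], frozenset(d["shared_mirnas"]))
            for d in payload["planted_pairs"]
        ]
        return cls(
            de_features=payload["de_features"],
            planted_pairs=pairs,
            hub_circ=payload["hub_circ"],
            config_fingerprint=payload["config_fingerprint"],
        )


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}-{i:05d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # variance mu + mu^2 * dispersion  <=>  shape 1/dispersion
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def _class_counts(
    rng: np.random.Generator, cfg: SynthConfig, ids: list[str], de_status: dict[str, str]
) -> pd.DataFrame:
    lo, hi = cfg.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ids)))
    fc = np.ones(len(ids))
    for i, fid in enumerate(ids):
        if fid in de_status:
            fc[i] = 2.0**cfg.de_log2fc if de_status[fid] == "UP" else 2.0**-cfg.de_log2fc
    nper = cfg.n_samples_per_group
    ctrl = np.column_stack(
        [_nb_draw(rng, base, cfg.nb_dispersion) for _ in range(nper)]
    )
    case = np.column_stack(
        [_nb_draw(rng, base * fc, cfg.nb_dispersion) for _ in range(nper)]
    )
    cols = [f"case_{j + 1}" for j in range(nper)] + [f"ctrl_{j + 1}" for j in range(nper)]
    return pd.DataFrame(np.column_stack([case, ctrl]), index=ids, columns=cols)


def _pick_de(rng: np.random.Generator, ids: list[str], frac: float) -> dict[str, str]:
    n_de = int(round(frac * len(ids)))
    chosen = rng.choice(len(ids), size=n_de, replace=False)
    chosen.sort()
    # alternate UP/DOWN for an even split
    return {ids[j]: ("UP" if k % 2 == 0 else "DOWN") for k, j in enumerate(chosen)}


def generate_counts(config: SynthConfig) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Draw per-class count matrices and the planted ground truth.

    Returns ({"mRNA": ..., "miRNA": ..., "circRNA": ...}, GroundTruth).
    Planted-DE features have a case/control group-mean ratio of
    2**de_log2fc (UP) or 2**-de_log2fc (DOWN) in expectation.  Planted
    competing pairs are chosen among planted-DE circRNAs and mRNAs, with
    shared-miRNA sets drawn from the planted-DE miRNAs; the first planted
    circRNA receives ~40% of the pairs and is recorded as the hub.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 11])
    all_ids = {
        "mRNA": _ids("MRNA", config.n_mrna),
        "miRNA": _ids("MIR", config.n_mirna),
        "circRNA": _ids("CIRC", config.n_circ),
    }
    de = {cls: _pick_de(rng, all_ids[cls], config.frac_de_of(cls)) for cls in CLASSES}
    nper = config.n_samples_per_group
    groups = {f"case_{j + 1}": "case" for j in range(nper)}
    groups |= {f"ctrl_{j + 1}": "control" for j in range(nper)}
    matrices = {
        cls: ExpressionMatrix(
            values=_class_counts(rng, config, all_ids[cls], de[cls]),
            groups=dict(groups),
            feature_class=cls,
            unit="counts",
        )
        for cls in CLASSES
    }

    pairs: list[PlantedPair] = []
    hub: str | None = None
    if config.n_planted_pairs:
        de_circ = sorted(de["circRNA"])
        de_mrna = sorted(de["mRNA"])
        de_mir = sorted(de["miRNA"])
        k = config.shared_mirnas_per_planted_pair
        if len(de_mrna) < config.n_planted_pairs:
            raise SynthConfigError(
                "not enough planted-DE mRNAs for distinct planted pairs"
            )
        if not de_circ:
            raise SynthConfigError("no planted-DE circRNAs to build pairs from")
        if k > len(de_mir):
            raise SynthConfigError(
                "shared_mirnas_per_planted_pair exceeds the planted-DE miRNA pool"
            )
        n_hub = max(1, int(round(HUB_PAIR_FRACTION * config.n_planted_pairs)))
        hub = de_circ[0]
        circ_seq = [hub] * n_hub
        others = de_circ[1:] or [hub]
        for j in range(config.n_planted_pairs - n_hub):
            circ_seq.append(others[j % len(others)])
        mrna_pick = rng.choice(len(de_mrna), size=config.n_planted_pairs, replace=False)
        for j, (c, gi) in enumerate(zip(circ_seq, mrna_pick)):
            shared = rng.choice(len(de_mir), size=k, replace=False)
            pairs.append(
                PlantedPair(
                    circ_id=c,
                    mrna_id=de_mrna[gi],
                    shared_mirnas=frozenset(de_mir[s] for s in shared),
                )
            )
    truth = GroundTruth(
        de_features=de,
        planted_pairs=pairs,
        hub_circ=hub,
        config_fingerprint=config.fingerprint(),
    )
    return matrices, truth


def generate_interactions(config: SynthConfig, truth: GroundTruth) -> InteractionSet:
    """Emit the miRNA-target interaction table realizing the ground truth.

    Each planted pair (circRNA, mRNA) shares exactly its planted miRNA set:
    planted edges are laid down first, Bernoulli(background_share_prob)
    edges added everywhere else, and any background edge that would raise a
    planted pair's shared count above the configured value is removed
    deterministically.  Genuine records get energies uniform in [-35, -20]
    kcal/mol; a decoy_frac fraction of extra records with energy above -20
    exercises the downstream energy filter.
    """
    config.validate()
    if truth.config_fingerprint != config.fingerprint():
        raise SynthConsistencyError("ground truth was generated from a different config")
    rng = np.random.default_rng([config.seed % (2**31), 23])
    mirnas = _ids("MIR", config.n_mirna)
    targets = [(t, "mRNA") for t in _ids("MRNA", config.n_mrna)] + [
        (t, "circRNA") for t in _ids("CIRC", config.n_circ)
    ]
    planted_edges: set[tuple[str, str]] = set()
    protected: dict[str, set[str]] = {}  # target -> miRNAs planted on it
    for p in truth.planted_pairs:
        for mi in p.shared_mirnas:
            for tgt in (p.circ_id, p.mrna_id):
                planted_edges.add((mi, tgt))
                protected.setdefault(tgt, set()).add(mi)

    draw = rng.random((len(mirnas), len(targets)))
    edges: dict[tuple[str, str], str] = {}
    for (mi, tgt) in sorted(planted_edges):
        cls = "circRNA" if tgt.startswith("CIRC") else "mRNA"
        edges[(mi, tgt)] = cls
    for i, mi in enumerate(mirnas):
        for j, (tgt, cls) in enumerate(targets):
            if (mi, tgt) in edges:
                continue
            if draw[i, j] < config.background_share_prob:
                edges[(mi, tgt)] = cls

    # enforce exact sharing for planted pairs: strip background edges that
    # create extra shared miRNAs (planted edges are never removed)
    for p in truth.planted_pairs:
        circ_mis = {mi for (mi, tgt) in edges if tgt == p.circ_id}
        mrna_mis = {mi for (mi, tgt) in edges if tgt == p.mrna_id}
        for mi in sorted((circ_mis & mrna_mis) - p.shared_mirnas):
            if mi not in protected.get(p.circ_id, set()):
                del edges[(mi, p.circ_id)]
            elif mi not in protected.get(p.mrna_id, set()):
                del edges[(mi, p.mrna_id)]
            else:  # pragma: no cover - impossible with distinct pair endpoints
                raise SynthConsistencyError(
                    f"cannot enforce exact sharing for pair {p.circ_id}-{p.mrna_id}"
                )

    keys = sorted(edges)
    energies = rng.uniform(-35.0, -20.0, size=len(keys))
    scores = rng.uniform(140.0, 180.0, size=len(keys))
    rows = [
        {
            "mirna_id": mi,
            "target_id": tgt,
            "target_class": edges[(mi, tgt)],
            "score": round(float(s), 2),
            "energy_kcal_mol": round(float(e), 2),
        }
        for (mi, tgt), e, s in zip(keys, energies, scores)
    ]

    n_decoys = int(round(config.decoy_frac * len(rows)))
    made = 0
    while made < n_decoys:
        i = int(rng.integers(len(mirnas)))
        j = int(rng.integers(len(targets)))
        mi, (tgt, cls) = mirnas[i], targets[j]
        if (mi, tgt) in edges:
            continue
        edges[(mi, tgt)] = cls
        rows.append(
            {
                "mirna_id": mi,
                "target_id": tgt,
                "target_class": cls,
                "score": round(float(rng.uniform(100.0, 140.0)), 2),
                "energy_kcal_mol": round(float(rng.uniform(-19.5, -5.0)), 2),
            }
        )
        made += 1

    df = pd.DataFrame(rows, columns=COLUMNS).sort_values(
        ["mirna_id", "target_id"], kind="mergesort"
    ).reset_index(drop=True)
    return InteractionSet(records=df)


def generate_gene_sets(
    config: SynthConfig,
    truth: GroundTruth,
    planted_term_size: int = 30,
    planted_de_fraction: float = 0.8,
    n_random_terms: int = 20,
):
    """GMT collection over the mRNA universe with one planted-enriched term.

    The planted term draws ``planted_de_fraction`` of its members from the
    planted-DE mRNAs (enriched by construction); the remaining terms are
    uniform random draws.  Raises if no DE mRNAs were planted.
    """
    from .enrichment import GeneSetCollection

    config.validate()
    if truth.config_fingerprint != config.fingerprint():
        raise SynthConsistencyError("ground truth was generated from a different config")
    de_mrna = sorted(truth.de_ids("mRNA"))
    if not de_mrna:
        raise SynthConsistencyError("no planted-DE mRNAs; planted term impossible")
    rng = np.random.default_rng([config.seed % (2**31), 37])
    all_mrna = _ids("MRNA", config.n_mrna)
    non_de = sorted(set(all_mrna) - set(de_mrna))

    n_from_de = min(len(de_mrna), int(round(planted_de_fraction * planted_term_size)))
    n_from_bg = min(len(non_de), planted_term_size - n_from_de)
    members = [de_mrna[i] for i in rng.choice(len(de_mrna), n_from_de, replace=False)]
    members += [non_de[i] for i in rng.choice(len(non_de), n_from_bg, replace=False)]
    sets = {"TERM-PLANTED": ("planted process (DE-enriched)", frozenset(members))}
    for t in range(1, n_random_terms + 1):
        size = int(rng.integers(15, 60))
        pick = rng.choice(len(all_mrna), size=size, replace=False)
        sets[f"TERM-{t:04d}"] = (
            f"random process {t}",
            frozenset(all_mrna[i] for i in pick),
        )
    return GeneSetCollection(sets=sets, background=frozenset(all_mrna))
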