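"""Seeded synthetic fixtures with planted statistical structure.

Real inputs to the screening funnel (curated bioactivity data, licensed
docking runs) cannot ship with the package, so every stage is exercised
against a generated world whose truth is known:

- compounds come from a fragment-decoration grammar over a fixed list of
  heteroaromatic scaffolds (6,912 distinct, valid structures);
- each compound has an underlying residue-contact *profile*: with class
  probability ``p_contact_active`` (actives) / ``p_contact_inactive``
  (inactives) a compound is a *carrier* of the planted signature — all
  signature residues on simultaneously, and off otherwise; the remaining
  (non-signature) residues are independent Bernoulli(``background_p``).
  The defaults 0.61 / 0.25 reproduce the observed 61% vs 25%
  signature-frequency contrast (ratio 2.44) of the RIPK1 analysis, and
  because every subset of the signature matches exactly the carrier set,
  the ratio-then-coverage-then-size selection rule recovers the full
  planted signature;
- per-pose contacts are the profile with independent flip noise
  (default 0: the noiseless stated world; tests of robustness turn it
  up explicitly), and per-pose docking scores are Gaussian per class.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from plifscreen.plif import (
    DEFAULT_POCKET_VOCABULARY,
    FOUR_RESIDUE_SIGNATURE,
    Pose,
    PoseContactTable,
)
from plifscreen.curation import ACTIVE, INACTIVE

# Fragment-decoration grammar: 6 asymmetric cores x 12 x 12 substituents
# x 8 tails = 6912 combinations, all parseable and InChIKey-distinct
# (verified by the test suite at the sizes used).
_CORES = (
    "c1c({s3})c({s1})cnc1{s2}",
    "c1cc({s1})c(nc1{s3})N{s2}",
    "c1ccc2c(c1{s3})cc({s1})n2{s2}",
    "O=C(N{s1})c1ccc({s2})c({s3})c1",
    "c1c({s3})sc({s1})c1C(=O)O{s2}",
    "c1nc({s1})sc1C({s3})N{s2}",
)
_SUBS = ("C", "CC", "CCC", "CCO", "CO", "CN", "N", "O", "F", "Cl", "C(C)C", "OC")
_TAILS = ("C", "CC", "CCN", "OC", "N", "CN", "F", "CCl")

GRAMMAR_SIZE = len(_CORES) * len(_SUBS) * len(_SUBS) * len(_TAILS)


def grammar_smiles(index: int) -> str:
    """Deterministic SMILES for a grammar index in [0, GRAMMAR_SIZE)."""
    if not 0 <= index < GRAMMAR_SIZE:
        raise ValueError(f"grammar index {index} out of range [0, {GRAMMAR_SIZE})")
    index, tail_i = divmod(index, len(_TAILS))
    index, s2_i = divmod(index, len(_SUBS))
    core_i, s1_i = divmod(index, len(_SUBS))
    return _CORES[core_i].format(s1=_SUBS[s1_i], s2=_SUBS[s2_i], s3=_TAILS[tail_i])


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic screening world.

    Class sizes, the joint signature-carrier probabilities (0.61 / 0.25,
    the observed active/inactive contrast), background contact
    probability for non-signature residues, pose count (50 in the real
    docking runs, 10 by default for speed), per-pose contact flip noise
    (0 by default — the noiseless stated world), the class-conditional
    score model, and the screening-library composition.
    """

    n_active: int = 300
    n_inactive: int = 300
    residue_vocabulary: tuple = DEFAULT_POCKET_VOCABULARY
    planted_signature: tuple = FOUR_RESIDUE_SIGNATURE
    p_contact_active: float = 0.61
    p_contact_inactive: float = 0.25
    background_p: float = 0.15
    n_poses: int = 10
    pose_flip_noise: float = 0.0
    score_mean_active: float = 60.0
    score_sd_active: float = 5.0
    score_mean_inactive: float = 55.0
    score_sd_inactive: float = 5.0
    library_size: int = 1000
    hit_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("p_contact_active", "p_contact_inactive", "background_p",
                     "pose_flip_noise", "hit_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_poses < 1:
            raise ValueError(f"n_poses must be >= 1, got {self.n_poses}")
        missing = set(self.planted_signature) - set(self.residue_vocabulary)
        if missing:
            raise ValueError(f"planted signature outside vocabulary: {sorted(missing)}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _profiles(rng, n: int, carrier_p: float, cfg: GeneratorConfig) -> np.ndarray:
    """Underlying contact profiles: (n, |vocab|) boolean matrix.

    Signature residues are on iff the compound is a carrier (drawn with
    ``carrier_p``); background applies to the other residues only.
    """
    vocab = list(cfg.residue_vocabulary)
    sig_idx = [vocab.index(r) for r in cfg.planted_signature]
    profiles = rng.random((n, len(vocab))) < cfg.background_p
    profiles[:, sig_idx] = False
    carriers = rng.random(n) < carrier_p
    profiles[np.ix_(carriers.nonzero()[0], sig_idx)] = True
    return profiles


def _pose_tables(rng, ids, profiles, labels, cfg: GeneratorConfig) -> list[PoseContactTable]:
    vocab = np.asarray(cfg.residue_vocabulary)
    tables = []
    for cid, profile, label in zip(ids, profiles, labels):
        if label == ACTIVE:
            mean, sd = cfg.score_mean_active, cfg.score_sd_active
        else:
            mean, sd = cfg.score_mean_inactive, cfg.score_sd_inactive
        scores = np.sort(rng.normal(mean, sd, size=cfg.n_poses))[::-1]
        flips = rng.random((cfg.n_poses, len(vocab))) < cfg.pose_flip_noise
        pose_bits = profile[None, :] ^ flips
        poses = [
            Pose(
                pose_index=i + 1,
                score=float(scores[i]),
                contacts=frozenset((r, "hydrophobic") for r in vocab[pose_bits[i]]),
            )
            for i in range(cfg.n_poses)
        ]
        tables.append(PoseContactTable(compound_id=cid, poses=poses))
    return tables


def simulate_labeled_set(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, list[PoseContactTable], np.ndarray]:
    """Generate a labeled training world: compounds, pose tables, labels.

    Returns ``(records, tables, labels)`` where ``records`` has columns
    ``compound_id, smiles, label`` plus the hidden truth column
    ``is_signature_carrier`` (evaluation only), and ``tables`` holds one
    :class:`PoseContactTable` per compound, aligned with ``records``.
    """
    cfg = config or GeneratorConfig()
    n_total = cfg.n_active + cfg.n_inactive
    if n_total > GRAMMAR_SIZE:
        raise ValueError(
            f"cannot generate {n_total} distinct compounds from a grammar of {GRAMMAR_SIZE}"
        )
    rng = np.random.default_rng(cfg.seed)
    smiles_idx = rng.choice(GRAMMAR_SIZE, size=n_total, replace=False)
    labels = np.array([ACTIVE] * cfg.n_active + [INACTIVE] * cfg.n_inactive)
    ids = [f"syn-{i:05d}" for i in range(n_total)]
    prof_a = _profiles(rng, cfg.n_active, cfg.p_contact_active, cfg)
    prof_i = _profiles(rng, cfg.n_inactive, cfg.p_contact_inactive, cfg)
    profiles = np.vstack([prof_a, prof_i]) if n_total else np.zeros((0, 0), bool)
    vocab = list(cfg.residue_vocabulary)
    sig_idx = [vocab.index(r) for r in cfg.planted_signature]
    records = pd.DataFrame(
        {
            "compound_id": ids,
            "smiles": [grammar_smiles(int(i)) for i in smiles_idx],
            "label": labels,
            "is_signature_carrier": profiles[:, sig_idx].all(axis=1),
        }
    )
    tables = _pose_tables(rng, ids, profiles, labels, cfg)
    return records, tables, labels


def simulate_library(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, list[PoseContactTable], pd.DataFrame]:
    """Generate an unlabeled screening library with a known hit fraction.

    Exactly ``round(library_size * hit_fraction)`` compounds carry the
    planted signature profile (placed at seeded random positions); the
    rest are background.  Returns ``(records, tables, truth)`` where
    ``truth`` (``compound_id, is_planted_hit``) is emitted separately
    and must only be used for evaluation.
    """
    cfg = config or GeneratorConfig()
    n = cfg.library_size
    if n > GRAMMAR_SIZE:
        raise ValueError(
            f"cannot generate {n} distinct compounds from a grammar of {GRAMMAR_SIZE}"
        )
    n_hits = int(round(n * cfg.hit_fraction))
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    smiles_idx = rng.choice(GRAMMAR_SIZE, size=n, replace=False)
    hit_pos = np.zeros(n, dtype=bool)
    hit_pos[rng.choice(n, size=n_hits, replace=False)] = True

    vocab = list(cfg.residue_vocabulary)
    sig_idx = [vocab.index(r) for r in cfg.planted_signature]
    profiles = rng.random((n, len(vocab))) < cfg.background_p
    profiles[:, sig_idx] = False
    profiles[np.ix_(hit_pos.nonzero()[0], sig_idx)] = True

    ids = [f"lib-{i:05d}" for i in range(n)]
    records = pd.DataFrame(
        {"compound_id": ids, "smiles": [grammar_smiles(int(i)) for i in smiles_idx]}
    )
    # library compounds get the "active"-class score model when planted
    pseudo_labels = np.where(hit_pos, ACTIVE, INACTIVE)
    tables = _pose_tables(rng, ids, profiles, pseudo_labels, cfg)
    truth = pd.DataFrame({"compound_id": ids, "is_planted_hit": hit_pos})
    return records, tables, truth


# Printed subset sizes of the assembled RIPK1 inhibitor dataset:
# 248 curated ChEMBL records + 72 Harris + 118 Roche, binarized to
# 312 actives / 126 inactives, balanced with 186 PubChem inactives
# sampled from a pool of 277 -> 624 total, 312 per class.
ASSEMBLY_SIZES = {"chembl": 248, "harris": 72, "roche": 118, "pubchem_pool": 277}
_ASSEMBLY_ACTIVES = {"chembl": 168, "harris": 60, "roche": 84}


def simulate_assembly_fixture(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Synthetic bioactivity tables mirroring the printed dataset bookkeeping.

    Emits four source tables with the published subset sizes: a curated
    ChEMBL-style table (248 records, all passing the default curation
    filters), Harris (72) and Roche (118) tables, and a PubChem inactive
    pool (277).  Active/inactive values are placed so the merged labeled
    set binarizes to 312 actives and 126 inactives; balancing then draws
    186 pool inactives for a 624-compound, 312/312 dataset.

    Structures are distinct across all tables, so standardization and
    deduplication leave every count unchanged.
    """
    rng = np.random.default_rng(seed)
    n_total = sum(ASSEMBLY_SIZES.values())
    smiles_idx = rng.choice(GRAMMAR_SIZE, size=n_total, replace=False)
    cursor = 0
    out: dict[str, pd.DataFrame] = {}
    for source, size in ASSEMBLY_SIZES.items():
        idx = smiles_idx[cursor:cursor + size]
        cursor += size
        n_active = _ASSEMBLY_ACTIVES.get(source, 0)
        values = np.concatenate(
            [
                rng.uniform(0.005, 1.8, size=n_active),          # below 2 uM
                rng.uniform(2.5, 90.0, size=size - n_active),    # above 2 uM
            ]
        )
        out[source] = pd.DataFrame(
            {
                "compound_id": [f"{source}-{i:04d}" for i in range(size)],
                "smiles": [grammar_smiles(int(i)) for i in idx],
                "value_um": values,
                "relation": "=",
                "measure": "IC50",
                "assay_type": "B",
                "confidence": 9,
                "organism": "Homo sapiens",
                "source": source,
            }
        )
    return out


def analytic_pass_probability(
    cfg: GeneratorConfig, top_n: int = 5, min_poses: int = 4, carrier: bool = True
) -> float:
    """Closed-form probability that a compound passes the planted-signature
    filter after robust-PLIF aggregation.

    Per residue, a profile-on bit survives aggregation with probability
    P(Binomial(top_n, 1 - flip) >= min_poses) and a profile-off bit
    false-fires with P(Binomial(top_n, flip) >= min_poses); a compound
    passes when all signature residues survive.  Non-carriers have all
    signature residues profile-off, so their pass probability is the
    false-fire probability to the power of the signature size (exactly 0
    at zero flip noise).
    """
    from scipy.stats import binom

    eps = cfg.pose_flip_noise
    k = len(cfg.planted_signature)
    p_on = float(binom.sf(min_poses - 1, top_n, 1 - eps))
    p_off = float(binom.sf(min_poses - 1, top_n, eps))
    return (p_on if carrier else p_off) ** k


@dataclass
class ADScenario:
    """Synthetic applicability-domain world (binary fingerprint space)."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_query: np.ndarray
    y_query: np.ndarray
    query_in_outlier_region: np.ndarray


def simulate_ad_scenario(
    seed: int = 0,
    n_train: int = 150,
    n_query: int = 80,
    n_bits: int = 128,
    outlier_fraction: float = 0.2,
    flip_p: float = 0.05,
) -> ADScenario:
    """Two dense, learnable clusters plus a sparse region of label noise.

    Actives cluster around prototype A and inactives around prototype B
    (bit-flip noise ``flip_p``); a low-density outlier region around a
    third prototype carries *random* labels, so cross-validated
    correctness is poor exactly where density is low.  Queries drawn
    from the same mixture let an applicability domain demonstrate its
    purpose: excluding the sparse noisy region raises precision among
    accepted predicted actives at the cost of coverage.
    """
    rng = np.random.default_rng(seed)
    protos = (rng.random((3, n_bits)) < 0.30)

    def draw(proto, n):
        flips = rng.random((n, n_bits)) < flip_p
        return proto[None, :] ^ flips

    def make(n):
        n_out = int(round(n * outlier_fraction))
        n_a = (n - n_out + 1) // 2
        n_b = n - n_out - n_a
        X = np.vstack([draw(protos[0], n_a), draw(protos[1], n_b), draw(protos[2], n_out)])
        y = np.array(
            [ACTIVE] * n_a
            + [INACTIVE] * n_b
            + [ACTIVE if rng.random() < 0.5 else INACTIVE for _ in range(n_out)]
        )
        in_outlier = np.array([False] * (n_a + n_b) + [True] * n_out)
        perm = rng.permutation(n)
        return X[perm].astype(np.uint8), y[perm], in_outlier[perm]

    X_train, y_train, _ = make(n_train)
    X_query, y_query, q_out = make(n_query)
    return ADScenario(
        X_train=X_train,
        y_train=y_train,
        X_query=X_query,
        y_query=y_query,
        query_in_outlier_region=q_out,
    )
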