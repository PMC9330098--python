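"""Protein-ligand interaction fingerprints (PLIFs) from docking poses.

A PLIF is a binary per-residue contact vector over a fixed binding-pocket
residue vocabulary.  To avoid biasing the fingerprint toward the single
top-scoring pose (whose score correlates poorly with activity), a residue
bit is set only when the residue is contacted, by any interaction type,
in at least ``min_poses`` of the ``top_n`` highest-scoring poses — the
"robust" PLIF.

Contacts come either from an external contact backend (PLIP/ProLIF-style
tables, ingested via the CSV schema ``compound_id, pose_index, score,
residue_id, interaction_type``) or from the simplified built-in geometric
detector in :func:`detect_contacts`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The six key pocket residues that interact with at least half of the
#: RIPK1 co-crystal ligands: binding-loop residues LEU70, VAL75, LEU78,
#: alphaE-helix residue LEU129, and the catalytic DLG-motif residues
#: ASP156 and LEU157.
DEFAULT_KEY_RESIDUES: tuple[str, ...] = (
    "LEU70", "VAL75", "LEU78", "LEU129", "ASP156", "LEU157",
)

#: The four-residue contact signature enriched in actives.
FOUR_RESIDUE_SIGNATURE: tuple[str, ...] = ("LEU70", "VAL75", "ASP156", "LEU157")

INTERACTION_TYPES = (
    "hydrophobic", "hbond_donor", "hbond_acceptor",
    "salt_bridge", "pi_stack", "halogen", "other",
)

_FILL_NAMES = (
    "GLY", "ALA", "VAL", "LEU", "ILE", "SER", "THR", "MET",
    "PHE", "TYR", "LYS", "ASP", "GLU", "ASN", "HIS",
)
_KEY_BY_NUM = {70: "LEU", 75: "VAL", 78: "LEU", 129: "LEU", 156: "ASP", 157: "LEU"}


def _build_default_vocabulary() -> tuple[str, ...]:
    # 81 pocket residues spanning the binding loop, alphaE helix and
    # activation loop; key residues pinned to their canonical names.
    numbers = list(range(64, 91)) + list(range(120, 141)) + list(range(145, 178))
    vocab = []
    for i, num in enumerate(numbers):
        name = _KEY_BY_NUM.get(num, _FILL_NAMES[i % len(_FILL_NAMES)])
        vocab.append(f"{name}{num}")
    return tuple(vocab)


#: Default 81-residue pocket vocabulary (includes the six key residues).
DEFAULT_POCKET_VOCABULARY: tuple[str, ...] = _build_default_vocabulary()


@dataclass(frozen=True)
class Pose:
    """One docking pose: index (1-based), fitness score, contact set.

    ``contacts`` holds ``(residue_id, interaction_type)`` pairs.
    """

    pose_index: int
    score: float
    contacts: frozenset

    def residues(self) -> frozenset:
        return frozenset(res for res, _ in self.contacts)


@dataclass
class PoseContactTable:
    """Per-pose residue contacts and docking scores for one compound."""

    compound_id: str
    poses: list[Pose] = field(default_factory=list)

    def sorted_poses(self) -> list[Pose]:
        """Poses by descending score, ties broken by ascending pose index."""
        return sorted(self.poses, key=lambda p: (-p.score, p.pose_index))

    def best_score(self) -> float:
        if not self.poses:
            raise ValueError(f"{self.compound_id}: no poses")
        return max(p.score for p in self.poses)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": self.compound_id,
                "pose_index": p.pose_index,
                "score": p.score,
                "residue_id": res,
                "interaction_type": itype,
            }
            for p in self.poses
            for res, itype in sorted(p.contacts)
        ]
        return pd.DataFrame(
            rows,
            columns=["compound_id", "pose_index", "score", "residue_id", "interaction_type"],
        )


def contact_tables_from_dataframe(df: pd.DataFrame) -> list[PoseContactTable]:
    """Parse the contact-table CSV schema into :class:`PoseContactTable` objects.

    Expected columns: ``compound_id, pose_index, score, residue_id,
    interaction_type``.  A pose with a score but no contacts may be
    encoded with an empty/NaN residue_id.
    """
    tables = []
    for cid, group in df.groupby("compound_id", sort=False):
        poses = []
        for (pidx, score), sub in group.groupby(["pose_index", "score"], sort=False):
            contacts = frozenset(
                (str(r), str(t))
                for r, t in zip(sub["residue_id"], sub["interaction_type"])
                if pd.notna(r) and str(r) != ""
            )
            poses.append(Pose(pose_index=int(pidx), score=float(score), contacts=contacts))
        tables.append(PoseContactTable(compound_id=str(cid), poses=poses))
    return tables


@dataclass
class InteractionFingerprint:
    """Binary per-residue contact vector aligned to a residue vocabulary."""

    vocabulary: tuple
    bits: np.ndarray

    def __post_init__(self):
        self.vocabulary = tuple(self.vocabulary)
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.vocabulary),):
            raise ValueError(
                f"bit vector length {self.bits.shape} does not match "
                f"vocabulary size {len(self.vocabulary)}"
            )

    @classmethod
    def from_residues(cls, on_residues: Iterable[str], vocabulary: Sequence[str]):
        vocabulary = tuple(vocabulary)
        on = set(on_residues)
        unknown = on - set(vocabulary)
        if unknown:
            raise ValueError(f"residues outside vocabulary: {sorted(unknown)}")
        bits = np.fromiter((1 if r in on else 0 for r in vocabulary), dtype=np.uint8)
        return cls(vocabulary=vocabulary, bits=bits)

    def on_residues(self) -> frozenset:
        return frozenset(r for r, b in zip(self.vocabulary, self.bits) if b)

    def to_series(self) -> pd.Series:
        return pd.Series(self.bits, index=list(self.vocabulary))


def robust_plif(
    table: PoseContactTable,
    top_n: int = 5,
    min_poses: int = 4,
    vocabulary: Sequence[str] = DEFAULT_POCKET_VOCABULARY,
) -> InteractionFingerprint:
    """Robust PLIF: residue bit on iff contacted in >= ``min_poses`` of the
    ``top_n`` highest-scoring poses (any interaction type counts).

    Raises ``ValueError`` when the table has fewer than ``min_poses``
    poses — the fingerprint is undefined rather than prorated.
    """
    if len(table.poses) < min_poses:
        raise ValueError(
            f"{table.compound_id}: {len(table.poses)} poses < min_poses={min_poses}; "
            "robust fingerprint undefined"
        )
    top = table.sorted_poses()[:top_n]
    counts: Counter = Counter()
    for pose in top:
        counts.update(pose.residues())
    vocab = tuple(vocabulary)
    vocab_set = set(vocab)
    unknown = set(counts) - vocab_set
    if unknown:
        raise ValueError(
            f"{table.compound_id}: contact residues outside vocabulary: {sorted(unknown)}"
        )
    bits = np.fromiter(
        (1 if counts.get(r, 0) >= min_poses else 0 for r in vocab), dtype=np.uint8
    )
    return InteractionFingerprint(vocabulary=vocab, bits=bits)


def plif_matrix(
    tables: Iterable[PoseContactTable],
    top_n: int = 5,
    min_poses: int = 4,
    vocabulary: Sequence[str] = DEFAULT_POCKET_VOCABULARY,
) -> pd.DataFrame:
    """Robust PLIFs for many compounds as a 0/1 DataFrame (rows = compounds)."""
    vocab = tuple(vocabulary)
    rows = {}
    for table in tables:
        fp = robust_plif(table, top_n=top_n, min_poses=min_poses, vocabulary=vocab)
        rows[table.compound_id] = fp.bits
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(vocab)).astype(np.uint8)


def plif_tanimoto(
    a: InteractionFingerprint,
    b: InteractionFingerprint,
    subset: Sequence[str] | None = None,
) -> float:
    """Tanimoto similarity |A & B| / |A | B| over on-bits, optionally
    restricted to a residue subset.  Defined as 0.0 when the restricted
    union is empty (no shared evidence).
    """
    if a.vocabulary != b.vocabulary:
        raise ValueError("fingerprints have different vocabularies")
    if subset is None:
        mask = np.ones(len(a.vocabulary), dtype=bool)
    else:
        subset_set = set(subset)
        unknown = subset_set - set(a.vocabulary)
        if unknown:
            raise ValueError(f"subset residues outside vocabulary: {sorted(unknown)}")
        mask = np.fromiter((r in subset_set for r in a.vocabulary), dtype=bool)
    abits = a.bits[mask].astype(bool)
    bbits = b.bits[mask].astype(bool)
    union = int(np.sum(abits | bbits))
    if union == 0:
        return 0.0
    return float(np.sum(abits & bbits)) / union


def similarity_percentile_cutoff(similarities, percentile: float = 80.0) -> float:
    """Similarity value at the requested percentile (linear interpolation).

    Compounds strictly above the returned threshold pass the similarity
    filter; the default 80th percentile reproduces the ">80th percentile"
    selection rule (which corresponded to similarities above 0.83 on the
    original ChEMBL docking data).
    """
    values = np.asarray(list(similarities), dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty similarity list")
    return float(np.percentile(values, percentile, method="linear"))


# ---------------------------------------------------------------------------
# Simplified built-in contact detector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """Minimal typed atom for the built-in geometric contact detector.

    ``neighbor`` is the position of a bonded heavy atom, used to compute
    the angle at a hydrogen-bond donor; detection falls back to the
    distance criterion alone when it is absent.
    """

    element: str
    coords: tuple
    residue_id: str | None = None
    is_apolar_carbon: bool = False
    is_donor: bool = False
    is_acceptor: bool = False
    neighbor: tuple | None = None


@dataclass
class ContactParams:
    """Geometric thresholds for the built-in detector (distances in Angstrom)."""

    hydrophobic_dist: float = 4.0
    hbond_dist: float = 3.5
    hbond_angle_deg: float = 120.0


def _dist(p, q) -> float:
    return math.dist(p, q)


def _angle_deg(center, a, b) -> float:
    va = np.asarray(a, dtype=float) - np.asarray(center, dtype=float)
    vb = np.asarray(b, dtype=float) - np.asarray(center, dtype=float)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    cosang = float(np.clip(np.dot(va, vb) / denom, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def detect_contacts(
    ligand_atoms: Sequence[Atom],
    protein_atoms: Sequence[Atom],
    params: ContactParams | None = None,
) -> frozenset:
    """Detect residue contacts for one ligand pose (simplified backend).

    Two rules, deliberately minimal (a pluggable stand-in for a full
    PLIP/ProLIF backend, whose tables are equally accepted upstream):

    - hydrophobic: apolar-carbon pair within ``hydrophobic_dist``;
    - hydrogen bond: donor-acceptor heavy-atom pair within ``hbond_dist``
      whose angle at the donor (bonded-neighbor -> donor -> acceptor) is
      at least ``hbond_angle_deg``; reported as ``hbond_donor`` when the
      ligand donates and ``hbond_acceptor`` when it accepts.

    Returns a frozenset of ``(residue_id, interaction_type)`` pairs.
    """
    params = params or ContactParams()
    contacts = set()
    for p_atom in protein_atoms:
        if p_atom.residue_id is None:
            raise ValueError("protein atom without residue annotation")
    for l_atom in ligand_atoms:
        for p_atom in protein_atoms:
            d = _dist(l_atom.coords, p_atom.coords)
            if (
                l_atom.is_apolar_carbon
                and p_atom.is_apolar_carbon
                and d <= params.hydrophobic_dist
            ):
                contacts.add((p_atom.residue_id, "hydrophobic"))
            if d <= params.hbond_dist:
                if l_atom.is_donor and p_atom.is_acceptor and _donor_angle_ok(
                    l_atom, p_atom, params
                ):
                    contacts.add((p_atom.residue_id, "hbond_donor"))
                if l_atom.is_acceptor and p_atom.is_donor and _donor_angle_ok(
                    p_atom, l_atom, params
                ):
                    contacts.add((p_atom.residue_id, "hbond_acceptor"))
    return frozenset(contacts)


def _donor_angle_ok(donor: Atom, acceptor: Atom, params: ContactParams) -> bool:
    if donor.neighbor is None:
        return True
    angle = _angle_deg(donor.coords, donor.neighbor, acceptor.coords)
    return angle >= params.hbond_angle_deg


def load_reference_fingerprint(path=None) -> InteractionFingerprint:
    """Load the reference-ligand interaction fingerprint.

    The packaged default is a synthetic stand-in for the 5HX6 co-crystal
    ligand PLIF (the real fingerprint requires licensed docking runs): it
    carries the six key residues plus a few supporting pocket contacts,
    over the default 81-residue vocabulary.  Ships as an editable CSV
    (columns ``residue_id, bit``) so a real reference can be dropped in.
    """
    if path is None:
        ref = resources.files("plifscreen").joinpath(
            "data/reference_plif_5hx6_synthetic.csv"
        )
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    vocab = tuple(df["residue_id"])
    bits = df["bit"].to_numpy(dtype=np.uint8)
    return InteractionFingerprint(vocabulary=vocab, bits=bits)
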