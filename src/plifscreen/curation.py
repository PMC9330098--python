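"""Bioactivity curation, structure standardization and molecular features.

The curation route mirrors common high-quality ChEMBL-style filtering for
binary classification of kinase inhibitors: keep high-confidence binding
assays on human protein with IC50/Ki/Kd readouts, binarize at a 2 uM
activity threshold, deduplicate standardized structures keeping the
minimum (most potent) value, and balance classes by sampling confirmed
inactives from a screening pool.

Tables are plain pandas DataFrames.  Bioactivity tables carry the columns
``compound_id, smiles, value_um, relation, measure, assay_type,
confidence, organism, source``; curated compound tables carry
``structure_key, smiles, label, heavy_atoms`` plus the source columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, FilterCatalog, QED, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from plifscreen._descriptor_panel import PHYSCHEM_NAMES

RDLogger.DisableLog("rdApp.*")

ACTIVE = "active"
INACTIVE = "inactive"
UNLABELED = "unlabeled"

VALID_RELATIONS = ("=", ">", "<")
VALID_MEASURES = ("IC50", "Ki", "Kd")

MORGAN_BITS = 1024
MORGAN_RADIUS = 2

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_BITS
)
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()
_tautomer_enumerator = rdMolStandardize.TautomerEnumerator()

_pains_params = FilterCatalog.FilterCatalogParams()
_pains_params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
_pains_catalog = FilterCatalog.FilterCatalog(_pains_params)


@dataclass
class CurationConfig:
    """Switches and thresholds for bioactivity record curation.

    Every filter can be disabled individually; defaults reproduce the
    strict ChEMBL curation used to assemble the RIPK1 inhibitor set.
    """

    min_confidence: int = 7          # strict: confidence must be > this
    assay_type: str = "B"
    organism: str = "Homo sapiens"
    measures: tuple[str, ...] = VALID_MEASURES
    activity_threshold_um: float = 2.0
    require_confidence: bool = True
    require_assay_type: bool = True
    require_organism: bool = True
    require_measure: bool = True
    require_relation: bool = True


def curate_bioactivity(
    records: pd.DataFrame, config: CurationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter raw bioactivity records to high-quality binding data.

    Keeps records with confidence strictly above ``min_confidence``,
    binding ("B") assays on the configured organism, IC50/Ki/Kd readouts,
    and an admissible relation: "=" always, ">" only when the censored
    bound is at or above the activity threshold, "<" only when it is at
    or below it.  Each rejected record carries exactly one reason (the
    first failing filter).

    Returns ``(kept, rejects)`` where ``rejects`` has a ``reason`` column.
    """
    config = config or CurationConfig()
    kept_idx: list[int] = []
    reject_idx: list[int] = []
    reasons: list[str] = []
    thr = config.activity_threshold_um

    for idx, row in records.iterrows():
        reason = _rejection_reason(row, config, thr)
        if reason is None:
            kept_idx.append(idx)
        else:
            reject_idx.append(idx)
            reasons.append(reason)

    kept = records.loc[kept_idx].copy()
    rejects = records.loc[reject_idx].copy()
    rejects["reason"] = reasons
    return kept, rejects


def _rejection_reason(row, config: CurationConfig, thr: float) -> str | None:
    if config.require_confidence:
        conf = row.get("confidence")
        if pd.isna(conf) or not int(conf) > config.min_confidence:
            return f"confidence not > {config.min_confidence}"
    if config.require_assay_type and row.get("assay_type") != config.assay_type:
        return f"assay_type != {config.assay_type}"
    if config.require_organism and row.get("organism") != config.organism:
        return f"organism != {config.organism}"
    if config.require_measure and row.get("measure") not in config.measures:
        return "measure not in " + "/".join(config.measures)
    if config.require_relation:
        relation = row.get("relation")
        value = row.get("value_um")
        if pd.isna(value):
            return "missing value"
        if relation not in VALID_RELATIONS:
            return f"malformed relation {relation!r}"
        if relation == ">" and value < thr:
            return f"'>' censored below threshold {thr}"
        if relation == "<" and value > thr:
            return f"'<' censored above threshold {thr}"
    return None


def binarize_activity(
    value_um: float | None, relation: str = "=", threshold_um: float = 2.0
) -> str:
    """Binarize a bioactivity value at the activity threshold (default 2 uM).

    A compound is active iff its effective value is strictly below the
    threshold.  "<"-censored records use the bound as effective value
    (so "<" at or below the threshold is active); ">"-censored records
    are inactive.  Missing values are unlabeled.
    """
    if value_um is None or (isinstance(value_um, float) and math.isnan(value_um)):
        return UNLABELED
    if value_um <= 0:
        raise ValueError(f"bioactivity value must be positive, got {value_um}")
    if relation == ">":
        return INACTIVE
    if relation == "<":
        return ACTIVE if value_um <= threshold_um else INACTIVE
    if relation == "=":
        return ACTIVE if value_um < threshold_um else INACTIVE
    raise ValueError(f"malformed relation {relation!r}")


def standardize_smiles(smiles: str) -> tuple[str, str, int]:
    """Standardize one structure; return (canonical SMILES, structure key, heavy atoms).

    Salt stripping (largest organic fragment), neutralization, and
    canonical tautomer selection, followed by an InChIKey structure key.
    Deterministic and idempotent.

    Raises ``ValueError`` on unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    mol = _tautomer_enumerator.Canonicalize(mol)
    key = Chem.MolToInchiKey(mol)
    return Chem.MolToSmiles(mol), key, mol.GetNumHeavyAtoms()


def standardize_and_dedupe(
    records: pd.DataFrame, threshold_um: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize structures and merge duplicates by structure key.

    Duplicates (same InChIKey after standardization) are merged keeping
    the minimum activity value among them — the most potent measurement
    wins.  Labels are (re)derived from the merged value.  Unparseable
    structures are returned in a rejects table, never silently dropped.

    Returns ``(compounds, rejects)``.
    """
    rows = []
    rejects = []
    for _, row in records.iterrows():
        try:
            smi, key, heavy = standardize_smiles(row["smiles"])
        except ValueError as exc:
            rej = row.to_dict()
            rej["reason"] = str(exc)
            rejects.append(rej)
            continue
        out = row.to_dict()
        out["smiles"] = smi
        out["structure_key"] = key
        out["heavy_atoms"] = heavy
        rows.append(out)

    if not rows:
        return (
            pd.DataFrame(columns=list(records.columns) + ["structure_key", "heavy_atoms"]),
            pd.DataFrame(rejects),
        )

    table = pd.DataFrame(rows)
    if "value_um" in table.columns:
        # keep the duplicate with the minimum value; stable for ties
        order = table["value_um"].fillna(np.inf)
        table = (
            table.assign(_order=order)
            .sort_values(["structure_key", "_order"], kind="stable")
            .drop_duplicates("structure_key", keep="first")
            .drop(columns="_order")
        )
        labels = [
            binarize_activity(v if pd.notna(v) else None, r, threshold_um)
            for v, r in zip(
                table["value_um"], table.get("relation", pd.Series("=", index=table.index))
            )
        ]
        table["label"] = labels
    else:
        table = table.drop_duplicates("structure_key", keep="first")
        table["label"] = UNLABELED
    table = table.reset_index(drop=True)
    return table, pd.DataFrame(rejects)


def balance_classes(
    actives: pd.DataFrame, inactive_pool: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Balance classes by sampling inactives without replacement from a pool.

    ``actives`` may already contain some inactives; only the shortfall is
    sampled.  Raises ``ValueError`` naming the shortfall when the pool is
    too small.  Reproducible under ``seed``.
    """
    n_active = int((actives["label"] == ACTIVE).sum())
    n_inactive = int((actives["label"] == INACTIVE).sum())
    need = n_active - n_inactive
    if need < 0:
        raise ValueError(
            f"more inactives ({n_inactive}) than actives ({n_active}); "
            "balancing by inactive sampling is not applicable"
        )
    if need > len(inactive_pool):
        raise ValueError(
            f"inactive pool too small: need {need}, have {len(inactive_pool)} "
            f"(shortfall {need - len(inactive_pool)})"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(inactive_pool), size=need, replace=False)
    sampled = inactive_pool.iloc[np.sort(take)].copy()
    sampled["label"] = INACTIVE
    out = pd.concat([actives, sampled], ignore_index=True)
    return out


def compute_features(smiles: str) -> tuple[pd.Series, np.ndarray]:
    """Compute the physchem descriptor panel and the 1024-bit Morgan fingerprint.

    The physchem panel is the frozen RDKit descriptor list (named, fixed
    order); the fingerprint is a radius-2, 1024-bit circular fingerprint.
    Non-finite descriptor values are mapped to 0 so the assembled feature
    matrix has no missing entries.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    values = Descriptors.CalcMolDescriptors(mol)
    phys = pd.Series([values[name] for name in PHYSCHEM_NAMES], index=PHYSCHEM_NAMES, dtype=float)
    phys = phys.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    fp = np.zeros(MORGAN_BITS, dtype=np.uint8)
    for bit in _morgan_gen.GetFingerprint(mol).GetOnBits():
        fp[bit] = 1
    return phys, fp


def compute_feature_matrix(smiles_list) -> tuple[pd.DataFrame, np.ndarray]:
    """Vectorized :func:`compute_features` over a SMILES sequence."""
    phys_rows = []
    fps = np.zeros((len(smiles_list), MORGAN_BITS), dtype=np.uint8)
    for i, smi in enumerate(smiles_list):
        phys, fp = compute_features(smi)
        phys_rows.append(phys)
        fps[i] = fp
    physchem = pd.DataFrame(phys_rows).reset_index(drop=True)
    return physchem, fps


def prefilter_library(
    records: pd.DataFrame, qed_min: float = 0.85, pains: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drug-likeness pre-filter for screening libraries.

    Keeps compounds with QED strictly above ``qed_min`` and (optionally)
    without PAINS substructure matches.  Returns the surviving records
    and per-filter removal counts.
    """
    keep = []
    counts = {"input": len(records), "qed_removed": 0, "pains_removed": 0}
    for idx, row in records.iterrows():
        mol = Chem.MolFromSmiles(row["smiles"])
        if mol is None:
            raise ValueError(f"unparseable SMILES: {row['smiles']!r}")
        if not QED.qed(mol) > qed_min:
            counts["qed_removed"] += 1
            continue
        if pains and _pains_catalog.HasMatch(mol):
            counts["pains_removed"] += 1
            continue
        keep.append(idx)
    counts["kept"] = len(keep)
    return records.loc[keep].copy(), counts
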