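"""Consensus hit selection and chemical-novelty quantification.

The screening funnel combines the two docking-derived rules (the mined
multi-residue contact signature and the PLIF-similarity-to-reference
filter, default cutoff strictly > 0.83) with the QSAR ensemble's
accepted active predictions.  Tier-1 hits satisfy both routes; the hit
list is backfilled from docking-only candidates ranked by the size of
their largest maximum common substructure (MCS) with a reference
inhibitor set, which doubles as the docking route's applicability
domain.  Novelty of the final hits is quantified by the fraction of
heavy atoms each hit shares with its nearest training compound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

from plifscreen.curation import ACTIVE
from plifscreen.signatures import SignatureRule, apply_signature_filter


def docking_rules_filter(
    fingerprints,
    rule: SignatureRule,
    similarities,
    sim_cutoff: float = 0.83,
    compound_ids=None,
) -> pd.DataFrame:
    """Apply the residue-signature and PLIF-similarity rules independently.

    Returns one row per compound with ``passes_signature``,
    ``plif_similarity``, ``passes_similarity`` (strictly above
    ``sim_cutoff``) and ``docking_candidate`` (both).  Missing
    similarities are flagged (``similarity_missing``) and fail the
    similarity rule, never silently pass.
    """
    passes_sig = apply_signature_filter(fingerprints, rule)
    sims = np.asarray(similarities, dtype=float)
    if sims.shape[0] != passes_sig.shape[0]:
        raise ValueError("fingerprints and similarities are not aligned")
    missing = np.isnan(sims)
    passes_sim = np.where(missing, False, sims > sim_cutoff)
    if compound_ids is None:
        compound_ids = np.arange(len(sims))
    return pd.DataFrame(
        {
            "compound_id": np.asarray(compound_ids),
            "passes_signature": passes_sig,
            "plif_similarity": sims,
            "similarity_missing": missing,
            "passes_similarity": passes_sim.astype(bool),
            "docking_candidate": passes_sig & passes_sim.astype(bool),
        }
    )


_DEFAULT_MCS_PARAMS = dict(
    bondCompareMode=rdFMCS.BondCompare.CompareOrder,
    ringMatchesRingOnly=True,
)


def mcs_anchor(
    query_smiles: str,
    reference_smiles,
    min_mcs_atoms: int = 1,
    timeout: int = 5,
) -> tuple[int, bool]:
    """Heavy-atom size of the largest MCS between a query and a reference set.

    Connected, bond-order-sensitive, ring-atoms-match-ring-atoms
    matching.  Returns ``(size, timed_out)`` where a hit of fewer than
    ``min_mcs_atoms`` atoms counts as 0 and ``timed_out`` marks the size
    as a lower bound (some per-pair search hit the ``timeout`` seconds).
    """
    query = Chem.MolFromSmiles(query_smiles)
    if query is None:
        raise ValueError(f"unparseable SMILES: {query_smiles!r}")
    best = 0
    any_timeout = False
    for ref_smi in reference_smiles:
        ref = Chem.MolFromSmiles(ref_smi)
        if ref is None:
            raise ValueError(f"unparseable SMILES: {ref_smi!r}")
        result = rdFMCS.FindMCS(
            [query, ref],
            timeout=timeout,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            ringMatchesRingOnly=True,
        )
        any_timeout = any_timeout or result.canceled
        if result.numAtoms >= min_mcs_atoms:
            best = max(best, result.numAtoms)
    return best, any_timeout


def mcs_anchor_sizes(
    query_smiles_list, reference_smiles, min_mcs_atoms: int = 1, timeout: int = 5
) -> pd.DataFrame:
    """:func:`mcs_anchor` over many queries; columns ``mcs_anchor_size, mcs_timed_out``."""
    sizes, flags = [], []
    for smi in query_smiles_list:
        size, timed_out = mcs_anchor(smi, reference_smiles, min_mcs_atoms, timeout)
        sizes.append(size)
        flags.append(timed_out)
    return pd.DataFrame({"mcs_anchor_size": sizes, "mcs_timed_out": flags})


def consensus_select(results: pd.DataFrame, k: int) -> pd.DataFrame:
    """Rank and select up to ``k`` hits by consensus tier.

    ``results`` must carry ``docking_candidate``, ``qsar_accepted_active``
    (accepted-within-AD QSAR active prediction), ``mcs_anchor_size`` and
    ``plif_similarity``.  Tier 1 is the intersection of docking
    candidates and accepted QSAR actives (kept in input order); the
    remainder is backfilled from docking-only candidates ranked by
    descending MCS anchor size, ties broken by larger similarity, then
    input order.  Warns (and returns everything) when fewer than ``k``
    candidates exist.
    """
    required = {"docking_candidate", "qsar_accepted_active", "mcs_anchor_size", "plif_similarity"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    results = results.reset_index(drop=True)
    docking = results["docking_candidate"].to_numpy(dtype=bool)
    qsar_ok = results["qsar_accepted_active"].to_numpy(dtype=bool)
    tier1 = results[docking & qsar_ok].copy()
    tier1["consensus_tier"] = "qsar∩docking"
    backfill_pool = results[docking & ~qsar_ok].copy()
    backfill_pool["consensus_tier"] = "docking-only"
    backfill_pool = backfill_pool.sort_values(
        ["mcs_anchor_size", "plif_similarity"], ascending=[False, False], kind="stable"
    )
    need = max(k - len(tier1), 0)
    selected = pd.concat([tier1.head(k), backfill_pool.head(need)], ignore_index=True)
    if len(selected) < k:
        warnings.warn(
            f"only {len(selected)} consensus candidates available for k={k}",
            stacklevel=2,
        )
    return selected


def novelty_report(
    hit_smiles,
    train_smiles,
    min_mcs_atoms: int = 3,
    timeout: int = 5,
    hit_ids=None,
    train_ids=None,
) -> pd.DataFrame:
    """For each hit, the training compound sharing the largest scaffold.

    Reports the MCS heavy-atom count and the shared heavy-atom fraction
    on both sides of the pair (``mcs_atoms / heavy_atoms``); a shared
    fraction near 1 means the hit re-discovers a known chemotype, while
    small fractions indicate new chemical space.  Pairs whose best MCS
    is below ``min_mcs_atoms`` report fractions of 0.0.
    """
    hit_smiles = list(hit_smiles)
    train_smiles = list(train_smiles)
    if hit_ids is None:
        hit_ids = list(range(len(hit_smiles)))
    if train_ids is None:
        train_ids = list(range(len(train_smiles)))
    train_mols = []
    for smi in train_smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        train_mols.append(mol)
    rows = []
    for hid, smi in zip(hit_ids, hit_smiles):
        query = Chem.MolFromSmiles(smi)
        if query is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        best_size, best_idx, timed_out = 0, None, False
        for i, ref in enumerate(train_mols):
            result = rdFMCS.FindMCS(
                [query, ref],
                timeout=timeout,
                bondCompare=rdFMCS.BondCompare.CompareOrder,
                ringMatchesRingOnly=True,
            )
            timed_out = timed_out or result.canceled
            if result.numAtoms > best_size:
                best_size, best_idx = result.numAtoms, i
        if best_size < min_mcs_atoms or best_idx is None:
            rows.append(
                {
                    "hit_id": hid,
                    "nearest_train_id": None,
                    "mcs_heavy_atoms": 0,
                    "shared_fraction_hit": 0.0,
                    "shared_fraction_train": 0.0,
                    "mcs_timed_out": timed_out,
                }
            )
            continue
        rows.append(
            {
                "hit_id": hid,
                "nearest_train_id": train_ids[best_idx],
                "mcs_heavy_atoms": best_size,
                "shared_fraction_hit": best_size / query.GetNumHeavyAtoms(),
                "shared_fraction_train": best_size
                / train_mols[best_idx].GetNumHeavyAtoms(),
                "mcs_timed_out": timed_out,
            }
        )
    return pd.DataFrame(rows)
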