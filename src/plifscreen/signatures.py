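"""Residue-signature mining and enrichment evaluation.

Given robust PLIFs for labeled compounds, enumerate all residue subsets
of the key-residue panel, score each subset by how much more frequently
actives contact *all* of its residues simultaneously than inactives do,
and select the best-supported rule.  On the RIPK1 key-residue panel
(6 residues, subset sizes 2-6) this enumeration yields 57 candidate
signatures, of which the four-residue combination LEU70 + VAL75 +
ASP156 + LEU157 is the published winner (61% of actives vs 25% of
inactives, a 2.5-fold contrast).

Any ranking score (docking score, ligand efficiency, PLIF similarity)
can be evaluated with :func:`enrichment_curve`: precision for actives
among the compounds above each percentile cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from plifscreen.curation import ACTIVE, INACTIVE
from plifscreen.plif import InteractionFingerprint


@dataclass(frozen=True)
class SignatureRule:
    """A residue subset with its active/inactive contact frequencies.

    ``ratio`` is freq_active / freq_inactive, with ``math.inf`` as the
    sentinel when no inactive matches; ``coverage`` equals freq_active
    (the fraction of actives the rule recalls).
    """

    residues: frozenset
    freq_active: float
    freq_inactive: float
    ratio: float
    coverage: float

    def sorted_residues(self) -> tuple:
        return tuple(sorted(self.residues))


def enumerate_signatures(
    residues: Sequence[str], min_size: int, max_size: int
) -> list[tuple]:
    """All residue subsets of each size in [min_size, max_size], exactly once.

    Deterministic order: by size, then lexicographically on the sorted
    residue tokens.  For the six key residues and sizes 2-6 this yields
    C(6,2)+...+C(6,6) = 57 subsets.
    """
    residues = sorted(set(residues))
    if not (1 <= min_size <= max_size <= len(residues)):
        raise ValueError(
            f"size bounds violated: need 1 <= {min_size} <= {max_size} <= {len(residues)}"
        )
    out = []
    for size in range(min_size, max_size + 1):
        out.extend(combinations(residues, size))
    return out


def _as_bit_frame(fingerprints) -> pd.DataFrame:
    if isinstance(fingerprints, pd.DataFrame):
        return fingerprints
    if len(fingerprints) and isinstance(fingerprints[0], InteractionFingerprint):
        vocab = fingerprints[0].vocabulary
        for fp in fingerprints:
            if fp.vocabulary != vocab:
                raise ValueError("fingerprints have inconsistent vocabularies")
        return pd.DataFrame(
            np.vstack([fp.bits for fp in fingerprints]), columns=list(vocab)
        )
    return pd.DataFrame(np.asarray(fingerprints))


def score_signature(subset, fingerprints, labels) -> SignatureRule:
    """Frequency of simultaneous contact with all subset residues, per class.

    ``fingerprints`` is a 0/1 DataFrame (columns = residue ids) or a list
    of :class:`InteractionFingerprint`; ``labels`` is aligned and must
    contain both classes.
    """
    subset = tuple(subset)
    if len(subset) == 0:
        raise ValueError("empty residue subset is not a signature")
    bits = _as_bit_frame(fingerprints)
    missing = [r for r in subset if r not in bits.columns]
    if missing:
        raise ValueError(f"subset residues absent from vocabulary: {missing}")
    labels = np.asarray(labels)
    is_active = labels == ACTIVE
    is_inactive = labels == INACTIVE
    n_active = int(is_active.sum())
    n_inactive = int(is_inactive.sum())
    if n_active == 0 or n_inactive == 0:
        raise ValueError(
            f"need both classes to score a signature (actives={n_active}, "
            f"inactives={n_inactive})"
        )
    matches = bits[list(subset)].to_numpy(dtype=bool).all(axis=1)
    freq_active = float(matches[is_active].mean())
    freq_inactive = float(matches[is_inactive].mean())
    ratio = freq_active / freq_inactive if freq_inactive > 0 else math.inf
    return SignatureRule(
        residues=frozenset(subset),
        freq_active=freq_active,
        freq_inactive=freq_inactive,
        ratio=ratio,
        coverage=freq_active,
    )


def select_best_signature(
    rules: Iterable[SignatureRule], min_coverage: float = 0.5
) -> SignatureRule:
    """Best rule: maximum active/inactive ratio among rules with coverage
    >= ``min_coverage``.

    Ties break toward higher coverage, then larger subsets, then
    lexicographically smaller residue tuples.  Raises when no rule meets
    the coverage floor.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("empty rule list")
    eligible = [r for r in rules if r.coverage >= min_coverage]
    if not eligible:
        raise ValueError(
            f"no signature reaches minimum coverage {min_coverage} "
            f"(best coverage {max(r.coverage for r in rules):.3f})"
        )
    # min over negated criteria so the final tie-break is plain
    # lexicographic order on the sorted residue tuple
    return min(
        eligible,
        key=lambda r: (-r.ratio, -r.coverage, -len(r.residues), r.sorted_residues()),
    )


def apply_signature_filter(fingerprints, rule: SignatureRule) -> np.ndarray:
    """Boolean mask: True where all rule residues' bits are on."""
    bits = _as_bit_frame(fingerprints)
    subset = rule.sorted_residues()
    missing = [r for r in subset if r not in bits.columns]
    if missing:
        raise ValueError(f"rule residues absent from vocabulary: {missing}")
    return bits[list(subset)].to_numpy(dtype=bool).all(axis=1)


def ligand_efficiency(score: float, heavy_atoms: int) -> float:
    """Docking score normalized by heavy-atom count (size correction)."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    return score / heavy_atoms


@dataclass
class EnrichmentCurve:
    """Precision for actives among compounds above each percentile cutoff.

    ``precision`` is NaN where the selection is empty (undefined, never
    reported as 0); ``n_selected`` is non-increasing as the cutoff
    tightens.
    """

    percentiles: np.ndarray
    precision: np.ndarray
    n_selected: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "precision": self.precision,
                "n_selected": self.n_selected,
            }
        )


def enrichment_curve(
    scores, labels, percentiles: Sequence[float] = tuple(range(0, 100, 5))
) -> EnrichmentCurve:
    """Enrichment of actives along a descending-better score ranking.

    At each percentile p, compounds scoring strictly above the p-th
    percentile of the score distribution are selected and the fraction of
    actives among them (precision x 100 = "% enrichment") is reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels are not aligned")
    pcts = np.asarray(list(percentiles), dtype=float)
    precision = np.full(pcts.shape, np.nan)
    n_selected = np.zeros(pcts.shape, dtype=int)
    for i, p in enumerate(pcts):
        cut = np.percentile(scores, p, method="linear")
        mask = scores > cut
        n = int(mask.sum())
        n_selected[i] = n
        if n > 0:
            precision[i] = float((labels[mask] == ACTIVE).mean())
    return EnrichmentCurve(percentiles=pcts, precision=precision, n_selected=n_selected)


class SignatureMiner(BaseEstimator):
    """Mine the most enriched residue-contact signature from labeled PLIFs.

    scikit-learn-style estimator: ``fit(X, y)`` enumerates all residue
    subsets of the configured sizes over the columns of ``X`` (a 0/1
    PLIF matrix), scores each, and stores the winner; ``predict(X)``
    applies the selected rule as a boolean pass mask.

    Parameters
    ----------
    min_size, max_size : subset size bounds (default 2-6).
    min_coverage : minimum fraction of actives a rule must cover to be
        eligible (default 0.5 — the published 61%-coverage winner
        qualifies comfortably).
    residues : optional explicit residue panel; defaults to all columns
        of the fitted matrix.

    Attributes
    ----------
    rule_ : SignatureRule — the selected signature.
    rules_ : list[SignatureRule] — all scored candidates, enumeration order.
    """

    def __init__(self, min_size: int = 2, max_size: int = 6,
                 min_coverage: float = 0.5, residues=None):
        self.min_size = min_size
        self.max_size = max_size
        self.min_coverage = min_coverage
        self.residues = residues

    def fit(self, X, y):
        bits = _as_bit_frame(X)
        panel = list(self.residues) if self.residues is not None else list(bits.columns)
        subsets = enumerate_signatures(panel, self.min_size, self.max_size)
        self.rules_ = [score_signature(s, bits, y) for s in subsets]
        self.rule_ = select_best_signature(self.rules_, self.min_coverage)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "rule_"):
            raise ValueError("SignatureMiner is not fitted")
        return apply_signature_filter(X, self.rule_)

    def rules_table(self) -> pd.DataFrame:
        """All scored rules as a DataFrame (residues, freqs, ratio, coverage)."""
        return pd.DataFrame(
            {
                "residues": ["+".join(r.sorted_residues()) for r in self.rules_],
                "freq_active": [r.freq_active for r in self.rules_],
                "freq_inactive": [r.freq_inactive for r in self.rules_],
                "ratio": [r.ratio for r in self.rules_],
                "coverage": [r.coverage for r in self.rules_],
            }
        )
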