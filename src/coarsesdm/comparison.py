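"""Model scoring and cross-treatment comparison.

AUC (presence-background, rank formulation), the two binarization
thresholds (minimum training presence; sensitivity-equals-specificity),
thresholded range areas and overprediction ratios, the niche-overlap
statistics Schoener's D, Hellinger-based similarity I, and relative rank
RR, and paired Wilcoxon signed-rank tests.

A cell is deemed suitable iff its predicted value is >= the threshold
(inclusive), so the minimum-training-presence threshold keeps every
training locality predicted present. Specificity is computed on background
points as pseudo-negatives, the standard presence-only surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .treatments import TREATMENTS


# ---------------------------------------------------------------------------
# Discrimination and thresholds


def compute_auc(presence_scores, background_scores) -> float:
    """Fraction of (presence, background) pairs ranked correctly, ties 1/2.

    Mann-Whitney rank formulation; invariant under strictly monotone
    transforms of the scores.
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need non-empty presence and background scores")
    ranks = stats.rankdata(np.r_[p, b])
    r1 = ranks[: p.size].sum()
    return float((r1 - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def threshold_min_training_presence(presence_scores) -> float:
    """Lowest predicted value among training presences."""
    p = np.asarray(presence_scores, float)
    if p.size == 0:
        raise ValueError("no training presences")
    return float(p.min())


def threshold_sens_eq_spec(presence_scores, background_scores) -> float:
    """Candidate threshold (from the sorted union of observed scores)
    minimizing |sensitivity - specificity|; ties -> lower threshold.

    Sensitivity = fraction of presences >= t; specificity = fraction of
    background scores < t.
    """
    p = np.sort(np.asarray(presence_scores, float))
    b = np.sort(np.asarray(background_scores, float))
    if p.size == 0 or b.size == 0:
        raise ValueError("need non-empty presence and background scores")
    cand = np.unique(np.r_[p, b])
    sens = 1.0 - np.searchsorted(p, cand, side="left") / p.size
    spec = np.searchsorted(b, cand, side="left") / b.size
    gap = np.abs(sens - spec)
    # ties (within float roundoff) resolve to the lowest threshold
    return float(cand[np.argmax(gap <= gap.min() + 1e-12)])


def predicted_area(grid: np.ndarray, threshold: float,
                   mask: np.ndarray | None = None) -> int:
    """Number of masked-in cells with value >= threshold."""
    g = np.asarray(grid, float)
    if mask is not None:
        g = g[np.asarray(mask, bool)]
    return int(np.count_nonzero(g >= threshold))


def area_ratio(area_treatment: float, area_true: float) -> float:
    """Predicted-area ratio relative to the true-locality model."""
    if area_true == 0:
        raise ValueError("true-locality predicted area is 0; ratio undefined")
    return area_treatment / area_true


# ---------------------------------------------------------------------------
# Niche overlap


def _normalized(grid: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    g = np.asarray(grid, float)
    if mask is not None:
        g = g[np.asarray(mask, bool)]
    g = g.ravel()
    total = g.sum()
    if not total > 0:
        raise ValueError("grid sums to zero over the mask")
    return g / total


def schoener_D(grid_a, grid_b, mask=None) -> float:
    """Schoener's D = 1 - 0.5 * sum |p_A - p_B| on mask-normalized grids."""
    pa, pb = _normalized(grid_a, mask), _normalized(grid_b, mask)
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def similarity_I(grid_a, grid_b, mask=None) -> float:
    """Hellinger-based similarity I = 1 - 0.5 * sum (sqrt p_A - sqrt p_B)^2."""
    pa, pb = _normalized(grid_a, mask), _normalized(grid_b, mask)
    return float(1.0 - 0.5 * ((np.sqrt(pa) - np.sqrt(pb)) ** 2).sum())


def _count_strict_inversions(b: np.ndarray) -> int:
    """Number of index pairs i < j with b[i] > b[j] (strict), exactly."""
    if len(b) < 2:
        return 0
    mid = len(b) // 2
    left, right = b[:mid], b[mid:]
    inv = _count_strict_inversions(left) + _count_strict_inversions(right)
    left = np.sort(left)
    # elements of the sorted left half strictly greater than each right value
    inv += int((len(left) - np.searchsorted(left, np.sort(right), side="right")).sum())
    return inv


def _tie_pairs(v: np.ndarray) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def relative_rank(grid_a, grid_b, mask=None) -> float:
    """Probability that the two surfaces order a random cell pair identically.

    Exact concordant-pair counting in O(n log n). Pairs tied in both
    surfaces count as agreement; pairs tied in exactly one count 1/2 — so
    a surface compared with itself scores exactly 1.
    """
    a = np.asarray(grid_a, float)
    b = np.asarray(grid_b, float)
    if mask is not None:
        m = np.asarray(mask, bool)
        a, b = a[m], b[m]
    a, b = a.ravel(), b.ravel()
    if a.shape != b.shape:
        raise ValueError("grids must share shape/mask")
    n = a.size
    if n < 2:
        raise ValueError("need at least two cells")
    n_pairs = n * (n - 1) // 2

    order = np.lexsort((b, a))
    d = _count_strict_inversions(b[order])
    ta, tb = _tie_pairs(a), _tie_pairs(b)
    tab = _tie_pairs(np.unique(np.column_stack([a, b]), axis=0, return_inverse=True)[1])
    t_either = ta + tb - tab          # tied in at least one surface
    c = n_pairs - t_either - d        # strictly concordant
    score = c + tab + 0.5 * (t_either - tab)
    return float(score / n_pairs)


# ---------------------------------------------------------------------------
# Paired tests


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without tied |differences|, the tie-corrected normal
    approximation otherwise. All-zero differences give p = 1 by convention.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-species bundle


@dataclass
class SpeciesComparison:
    """All metrics for one species: one row per treatment versus the
    true-locality reference model."""

    species_id: str
    table: pd.DataFrame

    @classmethod
    def build(cls, species_id: str, n_records: int,
              presence_scores: dict[str, np.ndarray],
              background_scores: dict[str, np.ndarray],
              logistic_grids: dict[str, np.ndarray],
              raw_grids: dict[str, np.ndarray],
              mask: np.ndarray,
              reference: str = "true_locality") -> "SpeciesComparison":
        """Assemble the comparison table from per-treatment predictions.

        ``presence_scores``/``background_scores`` are logistic predictions
        at training records and background cells; grids are full-extent
        predictions. Areas use the logistic grids; D and I use the raw
        grids (normalized over the mask); RR is rank-based so either works.
        """
        ref_areas = {}
        rows = []
        treatments = [reference] + [t for t in TREATMENTS if t != reference]
        for tr in treatments:
            pres, bg = presence_scores[tr], background_scores[tr]
            t_mtp = threshold_min_training_presence(pres)
            t_ses = threshold_sens_eq_spec(pres, bg)
            a_mtp = predicted_area(logistic_grids[tr], t_mtp, mask)
            a_ses = predicted_area(logistic_grids[tr], t_ses, mask)
            if tr == reference:
                ref_areas = {"mtp": a_mtp, "ses": a_ses}
            rows.append({
                "species_id": species_id,
                "treatment": tr,
                "n_records": n_records,
                "auc": compute_auc(pres, bg),
                "threshold_mtp": t_mtp,
                "threshold_ses": t_ses,
                "area_mtp": a_mtp,
                "area_ses": a_ses,
                "area_ratio_mtp": area_ratio(a_mtp, ref_areas["mtp"]),
                "area_ratio_ses": area_ratio(a_ses, ref_areas["ses"]),
                "I": similarity_I(raw_grids[tr], raw_grids[reference], mask),
                "D": schoener_D(raw_grids[tr], raw_grids[reference], mask),
                "RR": relative_rank(raw_grids[tr], raw_grids[reference], mask),
            })
        return cls(species_id=species_id, table=pd.DataFrame(rows))


def compare_species(species_id: str, n_records: int, presence_scores,
                    background_scores, logistic_grids, raw_grids, mask,
                    reference: str = "true_locality") -> SpeciesComparison:
    """Functional wrapper over :meth:`SpeciesComparison.build`."""
    return SpeciesComparison.build(species_id, n_records, presence_scores,
                                   background_scores, logistic_grids,
                                   raw_grids, mask, reference)
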