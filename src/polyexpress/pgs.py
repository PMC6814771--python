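"""Polygenic score computation, tuning-parameter selection and binning.

A weight set is a 3-column scoring file (snp_id, effect_allele, weight),
one per tuning parameter rho; the score is the weighted allele-dosage sum.
Candidate sets are competed on a held-out validation cohort by squared
Pearson correlation with the adjusted trait; the winner is applied to the
testing cohort, standardized on the variant-negative reference population,
and cut into 100 rank-based percentile bins (or within-subgroup tertiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class WeightSet:
    """SNP weights for one value of the tuning parameter rho."""

    rho: float
    entries: pd.DataFrame  # columns: snp_id, effect_allele, weight

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if self.entries["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in weight set")


def read_weight_file(path, rho: float) -> WeightSet:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["snp_id", "effect_allele", "weight"], header=0)
    return WeightSet(rho, df)


def write_weight_file(ws: WeightSet, path) -> None:
    ws.entries.to_csv(path, sep="\t", index=False)


def score(dosages: pd.DataFrame, weights: WeightSet) -> pd.Series:
    """Weighted dosage sum over the SNPs shared between panel and weights.

    Missing dosages are imputed with the SNP's sample-mean dosage; the
    number of missing entries is logged.
    """
    entries = weights.entries.set_index("snp_id")["weight"]
    shared = dosages.columns.intersection(entries.index)
    if len(shared) == 0:
        raise ValueError("no SNPs shared between dosage matrix and weight set")
    X = dosages[shared]
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        log.info("imputing %d missing dosages with per-SNP means", n_missing)
        X = X.fillna(X.mean())
    return pd.Series(X.to_numpy() @ entries[shared].to_numpy(),
                     index=dosages.index, name="score")


def tune_rho(candidates: list[WeightSet], dosages_val: pd.DataFrame,
             z_val: pd.Series) -> tuple[WeightSet, pd.DataFrame]:
    """Select the rho whose score best predicts the validation trait.

    R^2 is the squared Pearson correlation between score and adjusted trait
    on the validation cohort (0 for a constant score); ties go to the
    smaller rho.  Returns the winning set and the full R^2 table.
    """
    if not candidates:
        raise ValueError("need at least one candidate weight set")
    z = z_val.loc[dosages_val.index].to_numpy(dtype=float)
    rows = []
    for ws in candidates:
        s = score(dosages_val, ws).to_numpy()
        if np.std(s) == 0 or np.std(z) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(s, z)[0, 1] ** 2)
        rows.append((ws.rho, r2))
    table = pd.DataFrame(rows, columns=["rho", "r2"])
    best_r2 = table["r2"].max()
    best_rho = table.loc[np.isclose(table["r2"], best_r2), "rho"].min()
    best = next(ws for ws in candidates if ws.rho == best_rho)
    return best, table


def standardize_scores(scores: pd.Series, reference_ids) -> pd.Series:
    """Center/scale by the reference-population score moments."""
    ref = scores.loc[scores.index.intersection(pd.Index(reference_ids))]
    sd = ref.std(ddof=0)
    if sd == 0:
        raise ValueError("constant score on reference set")
    return (scores - ref.mean()) / sd


def _rank_bins(scores: pd.Series, member_ids, n_bins: int) -> pd.Series:
    """Stable rank-based bins on the member population, then map every other
    sample onto the same empirical cut points."""
    members = scores.loc[pd.Index(member_ids)]
    n = len(members)
    order = np.argsort(members.to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    member_bins = ranks * n_bins // n + 1
    out = pd.Series(index=scores.index, dtype=int, name="bin")
    out.loc[members.index] = member_bins
    others = scores.index.difference(members.index)
    if len(others):
        sorted_scores = members.to_numpy()[order]
        pos = np.searchsorted(sorted_scores, scores.loc[others].to_numpy(), side="right")
        pos = np.clip(pos - 1, 0, n - 1)
        out.loc[others] = pos * n_bins // n + 1
    return out


def percentile_bins(scores: pd.Series, binning_ids) -> pd.Series:
    """100 percentile bins defined on the binning population (the
    variant-negative testing cohort); carriers map onto the same cuts."""
    if len(binning_ids) < 100:
        raise ValueError("binning population must have at least 100 samples")
    return _rank_bins(scores, binning_ids, 100)


def tertiles(scores: pd.Series, subgroup_ids) -> pd.Series:
    """Rank thirds within one subgroup (e.g. carriers of a single RGD)."""
    if len(subgroup_ids) < 3:
        raise ValueError("subgroup must have at least 3 members")
    return _rank_bins(scores.loc[pd.Index(subgroup_ids)], subgroup_ids, 3)
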