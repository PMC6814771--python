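"""Sample inclusion and phenotype preparation.

Relatedness pruning removes one member of every first/second-degree pair
(PI_HAT > 0.1875) and breaks third-degree pairs (PI_HAT > 0.09875) only
when they fall inside a first-degree family network.  Phenotypes are
aggregated over EHR-style visits (median height and BMI, maximum LDL-C),
implausible heights are excluded, and traits are pre-adjusted for age, six
ancestry PCs and genotype batch separately by sex, then standardized to the
variant-negative reference population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PI_HAT_SECOND_DEGREE = 0.1875
PI_HAT_THIRD_DEGREE = 0.09875
PI_HAT_FIRST_DEGREE = 0.40  # network edges for pedigree-network proxy

TRAIT_AGGREGATION = {"height": "median", "BMI": "median", "LDL-C": "max"}


# ---------------------------------------------------------------------------
# Relatedness pruning
# ---------------------------------------------------------------------------

def first_degree_networks(pairs: pd.DataFrame) -> list[set]:
    """Connected components over pairs with PI_HAT above the first-degree
    bound; a cheap stand-in for pedigree reconstruction."""
    parent: dict = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for a, b in pairs.loc[pairs["pi_hat"] > PI_HAT_FIRST_DEGREE, ["id_a", "id_b"]].itertuples(index=False):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        parent[find(a)] = find(b)
    comps: dict = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return list(comps.values())


def prune_relatives(pairs: pd.DataFrame, sample_ids,
                    missing_counts: dict | None = None) -> set:
    """Return the kept sample set.

    Deterministic and independent of input pair order: violating pairs are
    processed in sorted order; within a pair, the member with more missing
    phenotypes is dropped, ties broken by dropping the lexicographically
    larger sample id.
    """
    kept = set(sample_ids)
    missing = missing_counts or {}

    viol = pairs[pairs["pi_hat"] > PI_HAT_SECOND_DEGREE]
    third = pairs[(pairs["pi_hat"] > PI_HAT_THIRD_DEGREE)
                  & (pairs["pi_hat"] <= PI_HAT_SECOND_DEGREE)
                  & pairs["in_first_degree_network"]]
    todo = sorted(
        {tuple(sorted((a, b))) for a, b in
         pd.concat([viol, third])[["id_a", "id_b"]].itertuples(index=False)}
    )
    for a, b in todo:
        if a in kept and b in kept:
            ma, mb = missing.get(a, 0), missing.get(b, 0)
            drop = a if (ma, a) > (mb, b) else b
            kept.discard(drop)
    return kept


# ---------------------------------------------------------------------------
# Phenotype aggregation and exclusions
# ---------------------------------------------------------------------------

def aggregate_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median height, median BMI and maximum documented LDL-C.

    Samples lacking all records for a trait get NaN there and drop out of
    that trait's analysis downstream.
    """
    parts = []
    for trait, how in TRAIT_AGGREGATION.items():
        sub = records[records["trait"] == trait]
        agg = sub.groupby("sample_id")["value"].median() if how == "median" \
            else sub.groupby("sample_id")["value"].max()
        parts.append(agg.rename(trait))
    return pd.concat(parts, axis=1).reset_index()


def apply_exclusions(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype- and ancestry-based exclusions with a reason log.

    A 10 cm height is a data-entry error; heights below 121 cm are excluded
    only when the amputation-related EHR code is also present; samples not
    of the reference genetic ancestry are excluded.
    """
    reasons = pd.Series("", index=samples.index, dtype=object)
    h = samples.get("height")
    if h is not None:
        reasons[h == 10.0] = "data_entry"
        amput = samples.get("amputation_code", pd.Series(False, index=samples.index))
        reasons[(h < 121.0) & amput.astype(bool) & (reasons == "")] = "amputation"
    if "european" in samples:
        reasons[~samples["european"].astype(bool) & (reasons == "")] = "non_european_ancestry"
    excluded = samples.loc[reasons != "", ["sample_id"]].assign(reason=reasons[reasons != ""])
    return samples[reasons == ""].copy(), excluded.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Covariate pre-adjustment and standardization
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(df))], ["intercept"]
    for c in covariates:
        if df[c].dtype == object or str(df[c].dtype) == "category":
            dummies = pd.get_dummies(df[c], prefix=c, drop_first=True)
            for name in dummies:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
        else:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the first column that adds no rank
    r = 0
    for j in range(X.shape[1]):
        rj = np.linalg.matrix_rank(X[:, : j + 1])
        if rj == r:
            raise ValueError(f"singular design: column {names[j]!r} is collinear")
        r = rj
    raise ValueError("singular design")


def preadjust_standardize(
    data: pd.DataFrame,
    trait: str,
    covariates: list[str],
    reference_ids,
) -> pd.DataFrame:
    """Sex-stratified covariate adjustment and z-standardization.

    Within each sex, a linear model of the trait on the covariates is fitted
    on the reference (variant-negative) samples only; all samples — carriers
    included — are residualized with those coefficients and standardized by
    the reference residual moments, so carriers cannot distort the null
    scale.  Returns sample_id, sex stratum, and the z-value.
    """
    ref = set(reference_ids)
    out = []
    for sex, grp in data.groupby("sex", sort=True):
        grp = grp.dropna(subset=[trait])
        X, names = _design(grp, covariates)
        y = grp[trait].to_numpy(dtype=float)
        in_ref = grp["sample_id"].isin(ref).to_numpy()
        if in_ref.sum() < X.shape[1] + 2:
            raise ValueError(f"reference set too small in sex stratum {sex}")
        _check_full_rank(X[in_ref], names)
        beta, *_ = np.linalg.lstsq(X[in_ref], y[in_ref], rcond=None)
        resid = y - X @ beta
        mu = resid[in_ref].mean()
        sd = resid[in_ref].std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero residual variance in sex stratum {sex}")
        out.append(pd.DataFrame({
            "sample_id": grp["sample_id"].to_numpy(),
            "trait": trait,
            "sex_stratum": sex,
            "z_value": (resid - mu) / sd,
        }))
    return pd.concat(out, ignore_index=True)
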