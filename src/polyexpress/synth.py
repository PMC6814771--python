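"""Synthetic cohort generator.

Emulates a health-system cohort of ~31,430 variant-negative adults plus
carriers of eleven rare genetic disorders (RGDs) spanning three quantitative
traits (height, BMI, LDL-C), together with the ancillary data every
downstream stage consumes: per-sample SNP-array intensity summaries
(median log-R ratio, B-allele-frequency heterozygosity), annotated variant
tables obeying (or deliberately violating) the curation rules, kinship
pairs, longitudinal phenotype records, ancestry PCs, genotype batch, and a
small SNP dosage panel whose true-weight score tracks the latent polygenic
value.

The standardized-trait model is additive and independent of carrier status:

    Z = sqrt(r2) * G + shift(RGD) + sqrt(1 - r2) * eps

with G, eps iid standard normal, r2 the fraction of trait variance the
polygenic score explains, and shift the carrier mean displacement in
trait-SD units.  Native-unit phenotypes are recovered through sex-specific
raw moments plus planted age/PC/batch confounder effects, so the
pre-adjustment stage has real work to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import expit, logit

# ---------------------------------------------------------------------------
# Default study conditions (trait moments, carrier groups, platforms)
# ---------------------------------------------------------------------------

#: Trait raw moments in native units; height is sex-specific.
DEFAULT_TRAIT_SPECS: dict[str, dict] = {
    "height": {
        "raw_mean": {"F": 161.94, "M": 176.69},
        "raw_sd": {"F": 6.66, "M": 7.20},
        "pgs_r2": 0.2171,
        "units": "cm",
    },
    "BMI": {
        "raw_mean": {"F": 31.94, "M": 31.94},
        "raw_sd": {"F": 7.72, "M": 7.72},
        "pgs_r2": 0.1078,
        "units": "kg/m2",
    },
    "LDL-C": {
        "raw_mean": {"F": 137.67, "M": 137.67},
        "raw_sd": {"F": 41.63, "M": 41.63},
        "pgs_r2": 0.0799,
        "units": "mg/dl",
    },
}

#: (label, trait, n_carriers, true shift in trait-SD units, required sex)
DEFAULT_RGD_SPECS: list[tuple] = [
    ("47,XXX", "height", 42, 0.93, "F"),
    ("47,XXY", "height", 44, 0.56, "M"),
    ("47,XYY", "height", 24, 1.32, "M"),
    ("45,X", "height", 19, -1.91, "F"),
    ("MC4R deficiency", "BMI", 58, 0.64, None),
    ("16p11.2 deletion", "BMI", 44, 1.34, None),
    ("16p11.2 duplication", "BMI", 50, -0.52, None),
    ("LDLR FH", "LDL-C", 146, 2.49, None),
    ("APOB FH", "LDL-C", 87, 1.42, None),
    ("PCSK9 FHBL", "LDL-C", 42, -0.72, None),
    ("APOB FHBL", "LDL-C", 53, -1.59, None),
]

ANEUPLOIDY_LABELS = {"45,X", "47,XXX", "47,XXY", "47,XYY"}

#: Of the 19 45,X-group carriers, 6 show complete-to-nearly-complete loss
#: (mosaic fraction >= 0.80) and 13 mosaic loss in [0.60, 0.80).
DEFAULT_45X_MIX = {"complete": 6, "mosaic": 13}

#: Platform reference minima: most negative X mLRR of a complete 45,X sample.
#: Chosen so the per-platform candidate screens (-0.28 HOEE, -0.20 GSA) fall
#: at a 45,X ratio of ~0.60 — the mosaic lower bound — as in the source data,
#: where the screen approximated the upper bound of the male X mLRR range.
DEFAULT_REF_MIN = {"HOEE": -0.47, "GSA": -0.34}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_variant_negative: int = 31430
    rgd_specs: list[tuple] = field(default_factory=lambda: list(DEFAULT_RGD_SPECS))
    trait_specs: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_SPECS.items()})
    n_snps: int = 1000
    snp_loading: float | None = None  # per-SNP corr with latent G; None -> sqrt(20/n_snps)
    platform_mix: float = 0.657  # fraction of samples on HOEE (59,499 of 90,561)
    ref_min: dict = field(default_factory=lambda: dict(DEFAULT_REF_MIN))
    x45_mix: dict = field(default_factory=lambda: dict(DEFAULT_45X_MIX))
    n_batches: int = 8
    n_related_pairs: int = 150
    n_third_degree_pairs: int = 60
    female_fraction: float = 0.577
    age_mean: float = 60.42
    age_sd: float = 12.0
    # confounders planted in native units per trait: age slope per decade (SD),
    # PC1 slope (SD), batch effect SD
    age_slope_sd_per_decade: float = -0.05
    pc1_slope_sd: float = 0.03
    batch_effect_sd: float = 0.02
    visit_noise_frac: float = 0.01  # measurement noise SD as fraction of raw mean
    mean_visits: float = 3.0  # visits per trait ~ 1 + Poisson(mean_visits)
    frac_high_chr1_sd: float = 0.02
    n_age_related_loss: int = 10
    statin_or: float = 3.0
    statin_base_prev: float = 0.41
    cad_or: float = 1.53
    cad_base_prev: float = 0.24
    frac_non_european: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_variant_negative < 0 or self.n_snps < 0:
            raise ValueError("counts must be non-negative")
        for frac in (self.platform_mix, self.female_fraction, self.frac_high_chr1_sd):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for trait, spec in self.trait_specs.items():
            if not 0.0 <= spec["pgs_r2"] <= 1.0:
                raise ValueError(f"pgs_r2 for {trait} outside [0, 1]")
            for sd in spec["raw_sd"].values():
                if sd <= 0:
                    raise ValueError(f"raw_sd for {trait} must be > 0")
        for label, trait, n, _shift, _sex in self.rgd_specs:
            if n < 0:
                raise ValueError(f"negative carrier count for {label}")
            if trait not in self.trait_specs:
                raise ValueError(f"unknown trait {trait} for {label}")


@dataclass
class Cohort:
    """Bundle of generated tables, keyed by sample_id throughout."""

    samples: pd.DataFrame      # one row per sample: sex, age, pcs, batch, ...
    phenotypes: pd.DataFrame   # long format: sample_id, trait, value, visit
    dosages: pd.DataFrame      # samples x SNPs, values in [0, 2]
    true_weights: pd.DataFrame  # snp_id, effect_allele, weight
    kinship: pd.DataFrame      # id_a, id_b, pi_hat, in_first_degree_network
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Light-weight standardized-trait simulator (shared by tests and acceptance)
# ---------------------------------------------------------------------------

def simulate_standardized_trait(
    n_controls: int,
    pgs_r2: float,
    rng: np.random.Generator,
    carrier_shifts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (z, g, carrier) on the standardized scale.

    z = sqrt(r2) g + shift + sqrt(1-r2) eps for carriers (shift per carrier),
    controls have shift 0.  Returns the trait z, latent polygenic value g and
    a 0/1 carrier indicator, controls first.
    """
    if not 0.0 <= pgs_r2 <= 1.0:
        raise ValueError("pgs_r2 must lie in [0, 1]")
    shifts = np.asarray([] if carrier_shifts is None else carrier_shifts, dtype=float)
    n = n_controls + shifts.size
    g = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    shift = np.concatenate([np.zeros(n_controls), shifts])
    z = np.sqrt(pgs_r2) * g + shift + np.sqrt(1.0 - pgs_r2) * eps
    carrier = np.concatenate([np.zeros(n_controls), np.ones(shifts.size)])
    return z, g, carrier


# ---------------------------------------------------------------------------
# Full cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the sample table, phenotypes, dosage panel and kinship pairs.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- sample frame ------------------------------------------------------
    n_carriers = sum(n for _, _, n, _, _ in config.rgd_specs)
    n = config.n_variant_negative + n_carriers
    width = max(6, len(str(n)))
    sample_id = np.array([f"S{i:0{width}d}" for i in range(n)])

    rgd_label = np.array([""] * n, dtype=object)
    shift_sd = np.zeros(n)
    trait_of_label = {}
    forced_sex = np.array([""] * n, dtype=object)
    pos = config.n_variant_negative
    for label, trait, n_car, shift, sex in config.rgd_specs:
        rgd_label[pos:pos + n_car] = label
        shift_sd[pos:pos + n_car] = shift
        trait_of_label[label] = trait
        if sex is not None:
            forced_sex[pos:pos + n_car] = sex
        pos += n_car

    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    sex = np.where(forced_sex != "", forced_sex, sex)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 95)
    pcs = rng.normal(0.0, 1.0, size=(n, 6))
    batch = np.array([f"B{b:02d}" for b in rng.integers(0, config.n_batches, n)])
    platform = np.where(rng.random(n) < config.platform_mix, "HOEE", "GSA")
    european = rng.random(n) >= config.frac_non_european

    latent_pgs = rng.standard_normal(n)

    samples = pd.DataFrame({
        "sample_id": sample_id,
        "sex": sex,
        "age": age,
        **{f"pc{i + 1}": pcs[:, i] for i in range(6)},
        "batch": batch,
        "platform": platform,
        "european": european,
        "latent_pgs": latent_pgs,
        "rgd_label": rgd_label,
        "amputation_code": np.zeros(n, dtype=bool),
    })

    # --- standardized traits and native-unit longitudinal records ----------
    batch_codes = pd.Categorical(batch).codes
    batch_fx = rng.normal(0.0, config.batch_effect_sd, config.n_batches)
    pheno_rows = []
    z_cols = {}
    for trait, spec in config.trait_specs.items():
        r2 = spec["pgs_r2"]
        eps = rng.standard_normal(n)
        shift = np.where([trait_of_label.get(l) == trait for l in rgd_label], shift_sd, 0.0)
        z = np.sqrt(r2) * latent_pgs + shift + np.sqrt(1.0 - r2) * eps
        z_cols[trait] = z

        mean = np.where(sex == "F", spec["raw_mean"]["F"], spec["raw_mean"]["M"])
        sd = np.where(sex == "F", spec["raw_sd"]["F"], spec["raw_sd"]["M"])
        confound = (
            config.age_slope_sd_per_decade * (age - config.age_mean) / 10.0
            + config.pc1_slope_sd * pcs[:, 0]
            + batch_fx[batch_codes]
        )
        native = mean + sd * (z + confound)

        n_visits = 1 + rng.poisson(config.mean_visits, n)
        noise_sd = config.visit_noise_frac * np.mean(list(spec["raw_mean"].values()))
        for i in range(n):
            vals = native[i] + rng.normal(0.0, noise_sd, n_visits[i])
            for v, val in enumerate(vals):
                pheno_rows.append((sample_id[i], trait, val, v))
    phenotypes = pd.DataFrame(pheno_rows, columns=["sample_id", "trait", "value", "visit"])

    # --- SNP dosage panel with a true-weight score tracking latent_pgs -----
    dosages, true_weights = _generate_dosages(latent_pgs, config, rng)
    dosages.index = pd.Index(sample_id, name="sample_id")

    # --- statin / CAD flags planted on the extreme LDL-C polygenic bin -----
    top_bin = latent_pgs >= np.quantile(latent_pgs, 0.99)
    statin_p = expit(logit(config.statin_base_prev) + np.log(config.statin_or) * top_bin)
    cad_p = expit(logit(config.cad_base_prev) + np.log(config.cad_or) * top_bin)
    samples["statin"] = rng.random(n) < statin_p
    samples["cad"] = rng.random(n) < cad_p

    for trait, z in z_cols.items():
        samples[f"true_z_{trait}"] = z  # kept for recovery tests; not an input to analyses

    kinship = _generate_kinship(sample_id[: config.n_variant_negative], config, rng)
    return Cohort(samples, phenotypes, dosages, true_weights, kinship, config)


def _generate_dosages(latent_pgs, config, rng):
    """Dosage panel in [0, 2] whose true-weight score is affine in latent G.

    Each SNP j has frequency p_j and a loading l on the shared factor; the
    standardized genotype is l*G + sqrt(1-l^2)*e, mapped to dosage scale.
    True per-dosage weights are sign_j * l / sqrt(2 p_j q_j), so the weighted
    sum concentrates on G as the panel grows.
    """
    n = latent_pgs.size
    m = config.n_snps
    p = rng.uniform(0.2, 0.8, m)
    sign = rng.choice([-1.0, 1.0], m)
    # keep the aggregate signal (sum of squared loadings ~ 20) independent of
    # panel size so the true-weight score stays tightly coupled to G
    load = config.snp_loading if config.snp_loading is not None else min(0.5, np.sqrt(20.0 / m))
    e = rng.standard_normal((n, m))
    x_std = sign[None, :] * (load * latent_pgs[:, None]) + np.sqrt(1 - load**2) * e
    scale = np.sqrt(2 * p * (1 - p))
    dos = np.clip(2 * p[None, :] + scale[None, :] * x_std, 0.0, 2.0)
    snp_ids = [f"rs{j + 1:06d}" for j in range(m)]
    alleles = rng.choice(list("ACGT"), m)
    weights = pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": alleles,
        "weight": sign * load / scale,
    })
    return pd.DataFrame(dos, columns=snp_ids), weights


def _generate_kinship(ids, config, rng):
    """Related pairs among variant-negative samples.

    First/second-degree pairs (PI_HAT > 0.1875) plus third-degree pairs, a
    subset of which sit inside a first-degree family network.
    """
    rows = []
    n_close = min(config.n_related_pairs, len(ids) // 2)
    n_third = min(config.n_third_degree_pairs, max(0, len(ids) // 2 - n_close))
    picked = rng.choice(len(ids), size=2 * (n_close + n_third), replace=False)
    k = 0
    for _ in range(n_close):
        a, b = picked[k], picked[k + 1]
        k += 2
        rows.append((ids[a], ids[b], rng.uniform(0.20, 0.55), True))
    for j in range(n_third):
        a, b = picked[k], picked[k + 1]
        k += 2
        rows.append((ids[a], ids[b], rng.uniform(0.10, 0.18), j % 2 == 0))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "pi_hat", "in_first_degree_network"])


def make_weight_family(
    true_weights: pd.DataFrame,
    rho_grid: list[float],
    rho_star: float,
    rng: np.random.Generator,
) -> dict[float, pd.DataFrame]:
    """Fabricate candidate weight sets, one per tuning parameter rho.

    Quality decays with distance from rho_star on the log scale: each set is
    q * true + (1 - q) * noise, so tuning on a validation cohort has a
    recoverable optimum at rho_star.
    """
    fam = {}
    sd = float(true_weights["weight"].std())
    for rho in rho_grid:
        if not 0.0 < rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        q = float(np.exp(-abs(np.log10(rho / rho_star))))
        w = q * true_weights["weight"].to_numpy() + (1 - q) * rng.normal(0, sd, len(true_weights))
        fam[rho] = true_weights.assign(weight=w)
    return fam


# ---------------------------------------------------------------------------
# Array intensity signals
# ---------------------------------------------------------------------------

def generate_array_signals(cohort: Cohort, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample array summaries: X/Y mLRR, chr1 LRR SD, X BAF het rate.

    Signal model (Gaussian noise around karyotype-specific means):

    * euploid complements are centred at 0 for the chromosomes they carry;
    * 45,X-group samples have mlrr_x = mosaic_fraction x platform reference
      minimum, and near-zero X heterozygosity (germline clonal loss);
    * gains sit at +0.15 on the gained chromosome (well past the +0.10
      calling threshold);
    * a configured fraction of samples get chr1 LRR SD above the 0.28 QC
      bound, and a few euploid females get an age-related-loss pattern (low
      X mLRR with preserved heterozygosity).
    """
    config = cohort.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    s = cohort.samples
    n = len(s)
    karyotype = np.where(s["sex"] == "F", "46,XX", "46,XY").astype(object)
    is_aneu = s["rgd_label"].isin(ANEUPLOIDY_LABELS).to_numpy()
    karyotype[is_aneu] = s.loc[is_aneu, "rgd_label"].to_numpy()

    # split the 45,X group into complete and mosaic per the configured mix
    mosaic_fraction = np.full(n, np.nan)
    idx45 = np.flatnonzero(karyotype == "45,X")
    n_complete = config.x45_mix.get("complete", 0)
    if len(idx45) and n_complete + config.x45_mix.get("mosaic", 0) != len(idx45):
        n_complete = int(round(len(idx45) * n_complete / max(1, sum(config.x45_mix.values()))))
    for j, i in enumerate(idx45):
        if j < n_complete:
            mosaic_fraction[i] = rng.uniform(0.85, 1.0)
        else:
            mosaic_fraction[i] = rng.uniform(0.62, 0.76)
            karyotype[i] = "45,X/46,XX"

    ref = np.array([config.ref_min[p] for p in s["platform"]])
    mlrr_x = rng.normal(0.0, 0.03, n)
    mlrr_y = np.where(s["sex"] == "M", rng.normal(0.0, 0.03, n), rng.normal(-1.0, 0.05, n))
    baf_het = np.clip(np.where(s["sex"] == "F", rng.normal(0.30, 0.02, n), rng.normal(0.01, 0.005, n)), 0, 1)

    loss = np.isin(karyotype, ["45,X", "45,X/46,XX"])
    mlrr_x[loss] = mosaic_fraction[loss] * ref[loss] + rng.normal(0.0, 0.01, loss.sum())
    baf_het[loss] = np.clip(rng.normal(0.01, 0.005, loss.sum()), 0, 1)

    gain_x = np.isin(karyotype, ["47,XXX", "47,XXY"])
    mlrr_x[gain_x] = rng.normal(0.15, 0.02, gain_x.sum())
    mlrr_y[karyotype == "47,XYY"] = rng.normal(0.15, 0.02, (karyotype == "47,XYY").sum())

    chr1_sd = np.clip(rng.normal(0.15, 0.04, n), 0.02, None)
    bad = rng.random(n) < config.frac_high_chr1_sd
    chr1_sd[bad] = rng.uniform(0.29, 0.50, bad.sum())

    # age-related X loss: low mLRR, heterozygosity preserved, euploid females
    cand = np.flatnonzero((karyotype == "46,XX") & ~bad)
    arl = rng.choice(cand, size=min(config.n_age_related_loss, cand.size), replace=False)
    mlrr_x[arl] = rng.uniform(1.01, 1.2, arl.size) * np.array(
        [min(-0.28, 0.6 * config.ref_min["HOEE"]) if p == "HOEE" else min(-0.20, 0.6 * config.ref_min["GSA"])
         for p in s["platform"].to_numpy()[arl]])
    karyotype[arl] = "46,XX(age-related loss)"

    return pd.DataFrame({
        "sample_id": s["sample_id"].to_numpy(),
        "platform": s["platform"].to_numpy(),
        "batch": s["batch"].to_numpy(),
        "ehr_sex": s["sex"].to_numpy(),
        "mlrr_x": mlrr_x,
        "mlrr_y": mlrr_y,
        "chr1_lrr_sd": chr1_sd,
        "baf_het_rate_x": baf_het,
        "true_karyotype": karyotype,
        "true_mosaic_fraction": mosaic_fraction,
    })


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_VARIANT_COLS = [
    "sample_id", "gene", "variant_type", "consequence",
    "affects_only_last_or_penultimate_exon", "clinvar_significance",
    "clinvar_stars", "protein_change", "qd", "dp", "allele_balance",
    "cnv_chrom", "cnv_start", "cnv_end", "cnv_copy_number",
]

# curated genomic anchors used by both generator and curation rules
REGION_16P11 = ("16", 29638675, 30188534)
REGION_MC4R = ("18", 60371350, 60372776)
REGION_LDLR_EX13_17 = ("19", 11116128, 11120586)


def _snv(sid, gene, consequence, sig="none", stars=0, protein=None,
         qd=35.0, dp=60, ab=0.5, last_exon=False):
    return dict(sample_id=sid, gene=gene, variant_type="SNV", consequence=consequence,
                affects_only_last_or_penultimate_exon=last_exon, clinvar_significance=sig,
                clinvar_stars=stars, protein_change=protein, qd=qd, dp=dp,
                allele_balance=ab, cnv_chrom=None, cnv_start=np.nan, cnv_end=np.nan,
                cnv_copy_number=np.nan)


def _cnv(sid, gene, chrom, start, end, cn):
    return dict(sample_id=sid, gene=gene, variant_type="CNV", consequence="copy_number",
                affects_only_last_or_penultimate_exon=False, clinvar_significance="none",
                clinvar_stars=0, protein_change=None, qd=np.nan, dp=0,
                allele_balance=0.5, cnv_chrom=chrom, cnv_start=start, cnv_end=end,
                cnv_copy_number=cn)


def generate_variant_table(
    cohort: Cohort,
    rng: np.random.Generator | None = None,
    include_decoys: bool = True,
) -> pd.DataFrame:
    """One curatable variant per SNV/CNV carrier, plus six decoy classes.

    Each decoy violates exactly one curation rule (one-star missense,
    start-loss, terminal-exon pLOF, 94%-overlap CNV, MC4R p.Leu328Ter, and a
    site-QC failure) so the filters can be exercised individually.
    Aneuploidy carriers get no variant rows; their labels come from the
    array-signal caller.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 2)
    rows: list[dict] = []
    s = cohort.samples
    for sid, label in zip(s["sample_id"], s["rgd_label"]):
        if not label or label in ANEUPLOIDY_LABELS:
            continue
        u = rng.random()
        if label == "LDLR FH":
            if u < 0.4:
                rows.append(_snv(sid, "LDLR", "stop_gained"))
            elif u < 0.8:
                rows.append(_snv(sid, "LDLR", "missense_variant", "P/LP", 2))
            else:
                c, a, b = REGION_LDLR_EX13_17
                rows.append(_cnv(sid, "LDLR", c, a, b, 3))
        elif label == "APOB FH":
            if u < 0.7:
                rows.append(_snv(sid, "APOB", "missense_variant", "P", 2, "p.Arg3527Gln"))
            else:
                rows.append(_snv(sid, "APOB", "missense_variant", "conflicting", 1, "p.Arg3527Trp"))
        elif label == "PCSK9 FHBL":
            rows.append(_snv(sid, "PCSK9", "frameshift_variant"))
        elif label == "APOB FHBL":
            rows.append(_snv(sid, "APOB", "stop_gained"))
        elif label == "MC4R deficiency":
            if u < 0.4:
                rows.append(_snv(sid, "MC4R", "stop_gained", protein="p.Tyr35Ter"))
            elif u < 0.8:
                rows.append(_snv(sid, "MC4R", "missense_variant", "LP", 2))
            else:
                c, a, b = REGION_MC4R
                rows.append(_cnv(sid, "MC4R", c, a - 200, b + 200, 1))
        elif label == "16p11.2 deletion":
            c, a, b = REGION_16P11
            rows.append(_cnv(sid, None, c, a - 1000, b + 1000, 1))
        elif label == "16p11.2 duplication":
            c, a, b = REGION_16P11
            rows.append(_cnv(sid, None, c, a - 1000, b + 1000, 3))
        else:
            raise ValueError(f"unknown RGD label {label!r}")

    if include_decoys:
        neg = s.loc[s["rgd_label"] == "", "sample_id"].to_numpy()
        dec = rng.choice(neg, size=6, replace=False)
        c, a, b = REGION_16P11
        length = b - a
        rows += [
            _snv(dec[0], "LDLR", "missense_variant", "P/LP", 1),       # one-star missense
            _snv(dec[1], "LDLR", "start_lost"),                         # start loss
            _snv(dec[2], "APOB", "frameshift_variant", last_exon=True),  # terminal exon
            _cnv(dec[3], None, c, a + int(0.06 * length), b, 1),        # 94% overlap
            _snv(dec[4], "MC4R", "stop_gained", protein="p.Leu328Ter"),  # functional receptor
            _snv(dec[5], "LDLR", "stop_gained", qd=2.0, dp=5, ab=0.5),   # site QC fail
        ]
    return pd.DataFrame(rows, columns=_VARIANT_COLS)


# ---------------------------------------------------------------------------
# Writers (seed recorded as a header comment line)
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)
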