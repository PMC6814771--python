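"""Gene-level curation rules assigning samples to eleven rare disorders.

SNV/indel curation: site QC (quality-by-depth, depth, allelic balance),
putative loss-of-function by consequence (high-impact, excluding start-loss
and variants confined to the last or penultimate exon of multi-exon genes),
and pathogenic missense restricted to ClinVar P/LP assertions with at least
two review stars, with a two-variant APOB whitelist (p.Arg3527Gln,
p.Arg3527Trp).  CNV curation: recurrent 16p11.2 BP4-BP5 events must overlap
at least 95% of the pathogenic region; an MC4R whole-gene deletion and the
LDLR exon 13-17 tandem duplication are recognised by interval overlap.
Sex-chromosome aneuploidy labels come from the array caller, with 45,X and
45,X/46,XX analysed as one group.
"""

from __future__ import annotations

import importlib.resources
import logging

import pandas as pd

from .synth import REGION_16P11, REGION_LDLR_EX13_17, REGION_MC4R

log = logging.getLogger(__name__)

HIGH_IMPACT = {
    "stop_gained", "frameshift_variant", "splice_acceptor_variant",
    "splice_donor_variant", "stop_lost", "transcript_ablation",
}
PLP = {"P", "LP", "P/LP"}

#: ClinVar-listed APOB FH missense variants included regardless of review
#: status (p.Arg3527Trp carries conflicting interpretations but multiple
#: pathogenic clinical assertions and no benign ones).
APOB_FH_WHITELIST = {"p.Arg3527Gln", "p.Arg3527Trp"}

#: MC4R stop-gain near the 3' end shown to leave a functioning receptor.
MC4R_BENIGN_PLOF = "p.Leu328Ter"

ANEUPLOIDY_CALL_TO_LABEL = {
    "45,X": "45,X",
    "45,X/46,XX": "45,X",  # combined group
    "47,XXX": "47,XXX",
    "47,XXY": "47,XXY",
    "47,XYY": "47,XYY",
}

LABEL_TRAIT = {
    "47,XXX": "height", "47,XXY": "height", "47,XYY": "height", "45,X": "height",
    "MC4R deficiency": "BMI", "16p11.2 deletion": "BMI", "16p11.2 duplication": "BMI",
    "LDLR FH": "LDL-C", "APOB FH": "LDL-C", "PCSK9 FHBL": "LDL-C", "APOB FHBL": "LDL-C",
}


def load_gene_rules() -> pd.DataFrame:
    """Bundled per-gene predicate table (terminal-exon rule applicability)."""
    with importlib.resources.files("polyexpress").joinpath("data/gene_rules.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


_GENE_RULES = None


def _terminal_exon_rule_applies(gene: str) -> bool:
    global _GENE_RULES
    if _GENE_RULES is None:
        _GENE_RULES = load_gene_rules().set_index("gene")
    if gene in _GENE_RULES.index:
        return bool(_GENE_RULES.loc[gene, "terminal_exon_rule"])
    return True


def site_qc(v) -> bool:
    """Sequencing site filters; True means the variant survives.

    Indels fail when QD < 5.0 and DP < 10; SNVs fail when QD < 3 and DP < 7;
    any variant with allelic balance below 0.15 fails.  Not applicable to
    CNVs.
    """
    if v["variant_type"] == "CNV":
        raise ValueError("site QC applies to SNVs/indels, not CNVs")
    if v["allele_balance"] < 0.15:
        return False
    if v["variant_type"] == "indel":
        return not (v["qd"] < 5.0 and v["dp"] < 10)
    return not (v["qd"] < 3 and v["dp"] < 7)


def is_plof(v) -> bool:
    """High-impact consequence, excluding start-loss and (where the gene
    rule applies) variants confined to the last or penultimate exon."""
    if v["consequence"] == "start_lost":
        return False
    if v["consequence"] not in HIGH_IMPACT:
        return False
    if v["affects_only_last_or_penultimate_exon"] and _terminal_exon_rule_applies(v["gene"]):
        return False
    return True


def is_reportable_missense(v) -> bool:
    """Missense with a P/LP assertion at >= 2 ClinVar stars, or on the APOB
    FH whitelist."""
    if v["consequence"] != "missense_variant":
        return False
    if v["gene"] == "APOB" and v.get("protein_change") in APOB_FH_WHITELIST:
        return True
    return v["clinvar_significance"] in PLP and v["clinvar_stars"] >= 2


def _overlap_fraction(start, end, region) -> float:
    _, rs, re_ = region
    if end < start:
        raise ValueError("malformed interval: end < start")
    return max(0, min(end, re_) - max(start, rs)) / (re_ - rs)


def classify_cnv_16p11(cnv_interval) -> str:
    """Recurrent 16p11.2 BP4-BP5 classification: >= 95% overlap of the
    pathogenic region, deletion if copy number < 2, duplication if > 2."""
    chrom, start, end, cn = cnv_interval
    if str(chrom).removeprefix("chr") != REGION_16P11[0]:
        return "none"
    frac = _overlap_fraction(start, end, REGION_16P11)
    if frac >= 0.95:
        if cn < 2:
            return "deletion"
        if cn > 2:
            return "duplication"
    return "none"


def _covers(start, end, region, min_frac=0.95) -> bool:
    return _overlap_fraction(start, end, region) >= min_frac


def curate_variant(v) -> str | None:
    """Pure per-variant predicate: the RGD label this variant supports."""
    if v["variant_type"] == "CNV":
        chrom = str(v["cnv_chrom"]).removeprefix("chr")
        iv = (chrom, v["cnv_start"], v["cnv_end"], v["cnv_copy_number"])
        if chrom == REGION_16P11[0]:
            kind = classify_cnv_16p11(iv)
            if kind == "deletion":
                return "16p11.2 deletion"
            if kind == "duplication":
                return "16p11.2 duplication"
            return None
        if chrom == REGION_MC4R[0] and v["cnv_copy_number"] < 2 \
                and _covers(v["cnv_start"], v["cnv_end"], REGION_MC4R):
            return "MC4R deficiency"
        if chrom == REGION_LDLR_EX13_17[0] and v["cnv_copy_number"] > 2 \
                and _covers(v["cnv_start"], v["cnv_end"], REGION_LDLR_EX13_17):
            return "LDLR FH"
        return None

    if not site_qc(v):
        return None
    gene = v["gene"]
    if gene == "LDLR":
        if is_plof(v) or is_reportable_missense(v):
            return "LDLR FH"
    elif gene == "APOB":
        if v["consequence"] == "missense_variant" and v.get("protein_change") in APOB_FH_WHITELIST:
            return "APOB FH"
        if is_plof(v):
            return "APOB FHBL"
    elif gene == "PCSK9":
        # gain-of-function FH variants deliberately not considered
        if is_plof(v):
            return "PCSK9 FHBL"
    elif gene == "MC4R":
        if v.get("protein_change") == MC4R_BENIGN_PLOF:
            return None
        if is_plof(v) or is_reportable_missense(v):
            return "MC4R deficiency"
    return None


def assign_rgds(variants: pd.DataFrame, karyotype_calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign disorder labels from curated variants plus karyotype calls.

    Returns one row per (sample, label) with the supporting rule.  Samples
    carrying both an FH and an FHBL label are contradictory for the LDL-C
    analysis and are flagged (``conflict`` column) with a logged warning.
    """
    rows = []
    for v in variants.to_dict("records"):
        try:
            label = curate_variant(v)
        except ValueError:
            label = None
        if label is not None:
            rule = "cnv_overlap" if v["variant_type"] == "CNV" else (
                "plof" if v["consequence"] != "missense_variant" else "missense_2star")
            rows.append((v["sample_id"], label, rule))
    if karyotype_calls is not None:
        for c in karyotype_calls.to_dict("records"):
            label = ANEUPLOIDY_CALL_TO_LABEL.get(c["karyotype"])
            if label is not None and c.get("qc_pass", True):
                rows.append((c["sample_id"], label, "karyotype_call"))
    out = pd.DataFrame(rows, columns=["sample_id", "rgd_label", "supporting_rule"])
    out = out.drop_duplicates(["sample_id", "rgd_label"]).reset_index(drop=True)

    out["trait"] = out["rgd_label"].map(LABEL_TRAIT)
    out["conflict"] = False
    per = out.groupby("sample_id")["rgd_label"].agg(set)
    fh = {"LDLR FH", "APOB FH"}
    fhbl = {"PCSK9 FHBL", "APOB FHBL"}
    bad = {sid for sid, labels in per.items() if labels & fh and labels & fhbl}
    if bad:
        log.warning("excluding %d sample(s) with contradictory FH and FHBL labels", len(bad))
        out.loc[out["sample_id"].isin(bad) & out["trait"].eq("LDL-C"), "conflict"] = True
    dup = out[~out["conflict"]].duplicated(["sample_id", "trait"], keep=False)
    if dup.any():
        log.warning("%d sample(s) carry multiple labels for one trait", dup.sum() // 2)
    return out
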