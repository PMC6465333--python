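"""RIP-qPCR enrichment calculus.

Implements the crossing-point (Cp) arithmetic used to quantify RNA
immunoprecipitation: enrichment relative to input RNA
(``100 * 2**((Cp_input - 6.644) - Cp_ip)``, "% input RNA", where 6.644 =
log2(100) corrects for the input dilution), mock-relative fold
enrichment (delta-delta-Cp between IP and mock), relative fold
enrichment between two genes, reference-gene-normalised relative
expression between conditions, and the minus-RT contamination QC (the
-RT control must sit at least 10 Cp above the +RT reaction).

Cp tables are long-format DataFrames with columns ``gene, role, rt,
bio_rep, tech_rep, cp`` (role in {input, ip, mock}; rt in {plus,
minus}; empty cp = not detected). A missing Cp is a distinct state, not
a sentinel number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

INPUT_CORRECTION = 6.644  # log2(100): input-dilution correction constant

CP_COLUMNS = ["gene", "role", "rt", "bio_rep", "tech_rep", "cp"]


class MissingCp(ValueError):
    """Raised when a required Cp value is not detected."""


def _check_cp(value, name: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingCp(f"{name} not detected")
    v = float(value)
    if v < 0:
        raise ValueError(f"{name} must be >= 0, got {v}")
    return v


def percent_input(cp_input, cp_ip, input_correction: float = INPUT_CORRECTION) -> float:
    """Enrichment relative to input RNA, in percent.

    ``100 * 2**((cp_input - input_correction) - cp_ip)``. The default
    correction 6.644 encodes a 1:100 effective input dilution; labs using a
    different input fraction override it.
    """
    ci = _check_cp(cp_input, "cp_input")
    cp = _check_cp(cp_ip, "cp_ip")
    return 100.0 * 2.0 ** ((ci - input_correction) - cp)


def fold_enrichment(
    cp_ip, cp_mock, cp_input_ip=None, cp_input_mock=None
) -> tuple[float, str]:
    """Mock-relative mRNA fold enrichment (delta-delta-Cp IP/mock).

    With both input Cps supplied, the input-normalised double delta
    ``2**((cp_mock - cp_input_mock) - (cp_ip - cp_input_ip))``; without
    them, the single-delta fallback ``2**(cp_mock - cp_ip)``. Returns
    ``(fold, method)`` where method labels which formula was used.
    """
    ip = _check_cp(cp_ip, "cp_ip")
    mock = _check_cp(cp_mock, "cp_mock")
    have_inputs = [cp_input_ip is not None, cp_input_mock is not None]
    if any(have_inputs) and not all(have_inputs):
        raise ValueError("supply both input Cps or neither")
    if all(have_inputs):
        d = (mock - _check_cp(cp_input_mock, "cp_input_mock")) - (
            ip - _check_cp(cp_input_ip, "cp_input_ip")
        )
        return 2.0**d, "double_delta"
    return 2.0 ** (mock - ip), "single_delta"


def relative_fold_enrichment(fe_target: float, fe_reference: float) -> float:
    """Fold enrichment of a target gene relative to a reference gene's."""
    if fe_reference <= 0:
        raise ValueError("reference fold enrichment must be > 0")
    return float(fe_target) / float(fe_reference)


def relative_expression(cp_target_c1, cp_ref_c1, cp_target_c2, cp_ref_c2) -> float:
    """Reference-gene-normalised expression of condition 1 vs condition 2.

    ``2**-((cp_target_c1 - cp_ref_c1) - (cp_target_c2 - cp_ref_c2))`` — the
    standard delta-delta-Cp expression ratio.
    """
    d1 = _check_cp(cp_target_c1, "cp_target_c1") - _check_cp(cp_ref_c1, "cp_ref_c1")
    d2 = _check_cp(cp_target_c2, "cp_target_c2") - _check_cp(cp_ref_c2, "cp_ref_c2")
    return 2.0 ** -(d1 - d2)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cp table missing columns: {missing}")
    dup = table.duplicated(subset=["gene", "role", "rt", "bio_rep", "tech_rep"])
    if dup.any():
        raise ValueError("duplicate (gene, role, rt, bio_rep, tech_rep) rows")
    return table


def rt_minus_qc(table: pd.DataFrame, min_gap: float = 10.0) -> pd.DataFrame:
    """Minus-RT contamination QC per (gene, role).

    A combination passes when the -RT Cp sits at least ``min_gap`` cycles
    above the matching +RT Cp (technical replicates averaged on the Cp
    scale first). A -RT reaction that never crossed threshold (missing cp)
    counts as a pass. Returns a report with columns gene, role, cp_plus,
    cp_minus, gap, passed.
    """
    _validate_table(table)
    if not (table["rt"] == "minus").any():
        import warnings

        warnings.warn("no -RT rows in table; contamination QC skipped", stacklevel=2)
        return pd.DataFrame(columns=["gene", "role", "cp_plus", "cp_minus", "gap", "passed"])
    rows = []
    for (gene, role), grp in table.groupby(["gene", "role"], sort=True):
        plus = grp.loc[grp["rt"] == "plus", "cp"].astype(float)
        minus = grp.loc[grp["rt"] == "minus", "cp"].astype(float)
        if plus.empty:
            continue
        cp_plus = plus.mean()
        if minus.empty or minus.isna().all():
            rows.append(dict(gene=gene, role=role, cp_plus=cp_plus, cp_minus=np.nan,
                             gap=np.inf, passed=True))
            continue
        cp_minus = minus.dropna().mean()
        gap = cp_minus - cp_plus
        rows.append(dict(gene=gene, role=role, cp_plus=cp_plus, cp_minus=cp_minus,
                         gap=gap, passed=bool(gap >= min_gap)))
    return pd.DataFrame(rows)


@dataclass
class EnrichmentRecord:
    gene: str
    statistic: str
    value: float
    sd: float | None
    per_replicate: list[float]
    note: str = ""


def _tech_averaged(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Cp scale per (gene, role, bio_rep)."""
    plus = table[table["rt"] == "plus"].dropna(subset=["cp"])
    return (
        plus.groupby(["gene", "role", "bio_rep"], sort=True)["cp"].mean().reset_index()
    )


def aggregate_replicates(
    table: pd.DataFrame,
    statistic: str = "percent_input",
    genes: list[str] | None = None,
    reference_gene: str | None = None,
    input_correction: float = INPUT_CORRECTION,
    apply_qc: bool = True,
) -> list[EnrichmentRecord]:
    """Replicate-aggregated enrichment statistics.

    Technical replicates are averaged on the Cp scale first; the statistic
    is then computed per biological replicate, and the mean and SD taken
    across biological replicates (per-replicate values are retained — the
    individual dots of a bar-with-dots plot). ``statistic`` is one of
    ``percent_input``, ``fold_enrichment`` (input-normalised when input Cp
    is present) or ``relative_fold_enrichment`` (requires
    ``reference_gene``). Combinations failing the -RT QC are excluded by
    default.
    """
    _validate_table(table)
    if statistic not in ("percent_input", "fold_enrichment", "relative_fold_enrichment"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "relative_fold_enrichment" and reference_gene is None:
        raise ValueError("relative_fold_enrichment requires reference_gene")

    work = table
    excluded_note = ""
    if apply_qc and (table["rt"] == "minus").any():
        qc = rt_minus_qc(table)
        failed = {(r.gene, r.role) for r in qc.itertuples() if not r.passed}
        if failed:
            keep = ~work.apply(lambda r: (r["gene"], r["role"]) in failed, axis=1)
            work = work[keep]
            excluded_note = f"QC-excluded: {sorted(failed)}"
    cp = _tech_averaged(work)

    def per_bio(gene: str, stat: str) -> list[float]:
        sub = cp[cp["gene"] == gene].pivot(index="bio_rep", columns="role", values="cp")
        vals = []
        for _, row in sub.iterrows():
            if stat == "percent_input":
                if pd.isna(row.get("input")) or pd.isna(row.get("ip")):
                    continue
                vals.append(percent_input(row["input"], row["ip"], input_correction))
            else:  # fold_enrichment
                if pd.isna(row.get("ip")) or pd.isna(row.get("mock")):
                    continue
                if "input" in row and not pd.isna(row.get("input")):
                    vals.append(
                        fold_enrichment(row["ip"], row["mock"], row["input"], row["input"])[0]
                    )
                else:
                    vals.append(fold_enrichment(row["ip"], row["mock"])[0])
        return vals

    gene_list = genes or sorted(cp["gene"].unique())
    records: list[EnrichmentRecord] = []
    for gene in gene_list:
        base_stat = "percent_input" if statistic == "percent_input" else "fold_enrichment"
        vals = per_bio(gene, base_stat)
        if statistic == "relative_fold_enrichment":
            ref_vals = per_bio(reference_gene, "fold_enrichment")
            if not ref_vals:
                records.append(EnrichmentRecord(gene, statistic, math.nan, None, [],
                                                note="reference gene incomputable"))
                continue
            ref = float(np.mean(ref_vals))
            vals = [relative_fold_enrichment(v, ref) for v in vals]
        if not vals:
            records.append(EnrichmentRecord(gene, statistic, math.nan, None, [],
                                            note="required role missing"))
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        note = excluded_note if len(vals) > 1 else (excluded_note + " single replicate: SD undefined").strip()
        records.append(
            EnrichmentRecord(gene, statistic, float(np.mean(vals)), sd, vals, note=note)
        )
    return records


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene=r.gene, statistic=r.statistic, value=r.value, sd=r.sd,
                 n_bio=len(r.per_replicate), note=r.note)
            for r in records
        ]
    )
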