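"""Deterministic covariate engineering for OCM-style episode tables.

Pure scalar functions mapping raw administrative fields onto the
analysis categories: the Hospital Referral Region (HRR) relative-cost
percentage, the six-level comorbidity category from counted HCC flags,
the three-level chemotherapy clean-period category, and the four-level
prescription-insurance category.  Apply them column-wise (e.g. with
``pandas.Series.map``) over a raw episode extract.
"""

from __future__ import annotations

NEW_ENROLLEE = "new_enrollee"


def hrr_relative_cost(avg_cost_hrr: float, avg_cost_all_hrr: float) -> float:
    """Percent deviation of an HRR's average episode cost from the all-HRR average.

    ``(avg_cost_hrr / avg_cost_all_hrr - 1) * 100``; scale-invariant in the
    pair of arguments.
    """
    if avg_cost_all_hrr <= 0:
        raise ValueError(
            f"avg_cost_all_hrr must be positive, got {avg_cost_all_hrr!r}"
        )
    return (avg_cost_hrr / avg_cost_all_hrr - 1.0) * 100.0


def categorize_comorbidity(hcc_flag_count: int | None = None, *, new_enrollee: bool = False) -> str:
    """Bin a prior-year HCC flag count into the six comorbidity categories.

    Counts 0-3 map to their own category, four and over collapse to "≥4",
    and beneficiaries without a prior-year claims history are
    "new_enrollee" regardless of any count supplied.
    """
    if new_enrollee:
        return NEW_ENROLLEE
    if hcc_flag_count is None:
        raise ValueError("hcc_flag_count required unless new_enrollee is set")
    if hcc_flag_count < 0:
        raise ValueError(f"hcc_flag_count must be >= 0, got {hcc_flag_count}")
    if hcc_flag_count >= 4:
        return "≥4"
    return str(int(hcc_flag_count))


def categorize_clean_period(days_since_last_chemo: int | None) -> str:
    """Bin days since the most recent prior chemotherapy claim.

    1-61 days, 62-730 days, or more than 730 days / no prior chemotherapy
    claim.  Day 731 falls in the top class so the three classes partition
    the positive integers.
    """
    if days_since_last_chemo is None:
        return ">730_or_none"
    days = int(days_since_last_chemo)
    if days <= 0:
        raise ValueError(f"days_since_last_chemo must be >= 1, got {days}")
    if days <= 61:
        return "1–61"
    if days <= 730:
        return "62–730"
    return ">730_or_none"


def categorize_insurance(
    part_d_enrolled: bool, low_income_subsidy: bool, full_medicaid: bool
) -> str:
    """Map Part D enrollment / low-income-subsidy / Medicaid flags to insurance category.

    Full Medicaid benefits imply the full-dual pathway (which includes
    Part D and LIS) regardless of the other flags.
    """
    if full_medicaid:
        return "FullDual"
    if not part_d_enrolled:
        return "NoPartD"
    if low_income_subsidy:
        return "PartD_LIS"
    return "PartD_NoLIS"
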