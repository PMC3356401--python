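"""Case-control association statistics for SNPs and SNP barcodes.

Everything reported about a barcode reduces to a 2x2 contingency table
of carrier status (carries the barcode / does not) against group
(case / control).  The carrier-predicts-case convention fixes the
classification cells: TP = case carriers, FP = control carriers,
FN = case non-carriers, TN = control non-carriers.  From the table we
derive

* odds ratio (ad/bc) with a Woolf log-scale 95% CI (z = 1.96), using the
  Haldane–Anscombe +0.5 correction when any cell is zero (flagged);
* risk ratio as the ratio of carrier prevalence in cases vs controls,
  a/(a+c) over b/(b+d);
* the five classification criteria: correctness (accuracy),
  sensitivity, specificity, PPV and NPV;
* a 1-df chi-square p-value with Yates continuity correction (the
  correction term floors at zero); Fisher's exact test is available as
  an alternative.

Protective barcodes — more carriers among controls — have OR < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as _sps

from .barcode_core import Barcode, ScoredBarcode, count_carriers
from .genotype_data import GenotypeDataset, GenotypeFrequencyTable

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "ClassificationScores",
    "BarcodeReport",
    "contingency",
    "contingency_from_counts",
    "odds_ratio",
    "risk_ratio",
    "classification_scores",
    "yates_chi2_p",
    "fisher_exact_p",
    "barcode_report",
    "single_snp_report",
]

Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier/non-carrier by case/control counts.

    ``a`` = case carriers (TP), ``b`` = control carriers (FP),
    ``c`` = case non-carriers (FN), ``d`` = control non-carriers (TN).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_case(self) -> int:
        return self.a + self.c

    @property
    def n_control(self) -> int:
        return self.b + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def difference(self) -> int:
        """Absolute case/control carrier difference (the search fitness)."""
        return abs(self.a - self.b)

    def swapped(self) -> "ContingencyTable":
        """Case and control columns exchanged."""
        return ContingencyTable(a=self.b, b=self.a, c=self.d, d=self.c)


def contingency(dataset: GenotypeDataset, barcode: Barcode) -> ContingencyTable:
    """Carrier 2x2 table of a barcode on a dataset."""
    a = count_carriers(dataset.case_matrix, barcode)
    b = count_carriers(dataset.control_matrix, barcode)
    return ContingencyTable(a=a, b=b, c=dataset.n_case - a, d=dataset.n_control - b)


def contingency_from_counts(
    case_carriers: int, control_carriers: int, n_case: int, n_control: int
) -> ContingencyTable:
    return ContingencyTable(
        a=case_carriers,
        b=control_carriers,
        c=n_case - case_carriers,
        d=n_control - control_carriers,
    )


@dataclass(frozen=True)
class OddsRatioResult:
    value: float
    ci_low: float
    ci_high: float
    zero_cell_corrected: bool = False


def odds_ratio(t: ContingencyTable) -> OddsRatioResult:
    """OR = ad/bc with Woolf 95% CI.

    A zero anywhere in the table switches to Haldane–Anscombe: 0.5 added
    to every cell, and the result flagged as corrected.
    """
    corrected = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = (
        (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
        if corrected
        else (t.a, t.b, t.c, t.d)
    )
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        value=value,
        ci_low=value * math.exp(-Z_95 * se),
        ci_high=value * math.exp(Z_95 * se),
        zero_cell_corrected=corrected,
    )


def risk_ratio(t: ContingencyTable) -> float:
    """Carrier prevalence in cases over carrier prevalence in controls.

    With equal group sizes this reduces to a/b.  No carriers in either
    group gives NaN; carriers only in cases gives +inf.
    """
    if t.b == 0:
        return math.nan if t.a == 0 else math.inf
    return (t.a / t.n_case) / (t.b / t.n_control)


@dataclass(frozen=True)
class ClassificationScores:
    correctness: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    degenerate: bool = False

    @property
    def sens_plus_spec(self) -> float:
        return self.sensitivity + self.specificity

    @property
    def ppv_plus_npv(self) -> float:
        return self.ppv + self.npv


def classification_scores(t: ContingencyTable) -> ClassificationScores:
    """Accuracy, sensitivity, specificity, PPV and NPV under
    carrier-predicts-case.  0/0 ratios return 0 and set the degenerate
    flag."""
    if t.n_case == 0 or t.n_control == 0:
        raise ValueError("both groups must be non-empty")

    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    return ClassificationScores(
        correctness=(t.a + t.d) / t.n,
        sensitivity=t.a / t.n_case,
        specificity=t.d / t.n_control,
        ppv=ratio(t.a, t.a + t.b),
        npv=ratio(t.d, t.c + t.d),
        degenerate=degenerate,
    )


def yates_chi2_p(t: ContingencyTable) -> float:
    """Continuity-corrected 1-df chi-square p-value.

    chi2 = n (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d)); the corrected
    numerator floors at 0, and any zero margin returns p = 1 (degenerate
    table).
    """
    margins = (t.a + t.b, t.c + t.d, t.n_case, t.n_control)
    if 0 in margins:
        return 1.0
    num = abs(t.a * t.d - t.b * t.c) - t.n / 2
    if num < 0:
        num = 0.0
    chi2 = t.n * num**2 / math.prod(margins)
    return float(_sps.chi2.sf(chi2, df=1))


def fisher_exact_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (alternative to the chi-square)."""
    return float(_sps.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])


@dataclass(frozen=True)
class BarcodeReport:
    """All reported statistics of one barcode."""

    barcode: Barcode | None
    table: ContingencyTable
    scores: ClassificationScores
    risk_ratio: float
    odds_ratio: OddsRatioResult
    p_value: float

    @property
    def difference(self) -> int:
        return self.table.difference

    def to_dict(self) -> dict:
        return {
            "barcode": None if self.barcode is None else str(self.barcode),
            "case_carriers": self.table.a,
            "control_carriers": self.table.b,
            "difference": self.difference,
            "correctness": self.scores.correctness,
            "sens_plus_spec": self.scores.sens_plus_spec,
            "ppv_plus_npv": self.scores.ppv_plus_npv,
            "risk_ratio": self.risk_ratio,
            "odds_ratio": self.odds_ratio.value,
            "or_ci_low": self.odds_ratio.ci_low,
            "or_ci_high": self.odds_ratio.ci_high,
            "p_value": self.p_value,
        }


def barcode_report(
    dataset_or_table: GenotypeDataset | ContingencyTable,
    barcode: Barcode | ScoredBarcode | None = None,
    exact: bool = False,
) -> BarcodeReport:
    """Full statistics for a barcode (or a pre-built 2x2 table).

    ``exact=True`` swaps the Yates chi-square for Fisher's exact test.
    """
    if isinstance(dataset_or_table, ContingencyTable):
        t = dataset_or_table
        bc = barcode.barcode if isinstance(barcode, ScoredBarcode) else barcode
    else:
        if isinstance(barcode, ScoredBarcode):
            bc = barcode.barcode
            t = contingency_from_counts(
                barcode.case_carriers,
                barcode.control_carriers,
                dataset_or_table.n_case,
                dataset_or_table.n_control,
            )
        else:
            bc = barcode
            t = contingency(dataset_or_table, barcode)
    return BarcodeReport(
        barcode=bc,
        table=t,
        scores=classification_scores(t),
        risk_ratio=risk_ratio(t),
        odds_ratio=odds_ratio(t),
        p_value=fisher_exact_p(t) if exact else yates_chi2_p(t),
    )


def single_snp_report(table: GenotypeFrequencyTable) -> pd.DataFrame:
    """Per-SNP, per-genotype effect estimates with genotype 1 as reference.

    For each SNP and genotype g in {2, 3}, the 2x2 table
    (case_g, control_g / case_1, control_1) yields an OR, Woolf 95% CI
    and Yates p-value.  Returns one row per (SNP, genotype) contrast.
    """
    rows = []
    for snp in table.snps:
        ref_case, ref_control = snp.case_counts[0], snp.control_counts[0]
        for g in (2, 3):
            t = ContingencyTable(
                a=snp.case_counts[g - 1],
                b=snp.control_counts[g - 1],
                c=ref_case,
                d=ref_control,
            )
            orr = odds_ratio(t)
            rows.append(
                {
                    "snp_index": snp.index,
                    "rs_id": snp.rs_id,
                    "gene": snp.gene,
                    "genotype": g,
                    "genotype_label": snp.genotype_labels[g - 1],
                    "case_count": snp.case_counts[g - 1],
                    "control_count": snp.control_counts[g - 1],
                    "odds_ratio": orr.value,
                    "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high,
                    "p_value": yates_chi2_p(t),
                    "zero_cell_corrected": orr.zero_cell_corrected,
                }
            )
    return pd.DataFrame(rows)
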