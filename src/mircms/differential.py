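"""Two-library differential expression of miRNA counts.

Counts are normalised to reads-per-million against each library's total
clean reads; a zero count receives the fixed pseudo-expression 0.01 on the
normalised scale.  Fold change is log2(WA/WB).  Significance comes from the
two-sided Audic-Claverie test for digital counts (Fisher's exact test is the
pluggable alternative); calls use raw p <= alpha and |log2FC| >= 1, with
Benjamini-Hochberg q-values reported alongside but not used for calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from scipy.special import betainc
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass
class DEConfig:
    alpha: float = 0.05
    fc_threshold: float = 1.0   # log2 units
    pseudo: float = 0.01
    test: str = "audic_claverie"   # or "fisher"
    adjust: str = "BH"             # reported; never used for calls

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.test not in ("audic_claverie", "fisher"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class NormalizedExpression:
    mirna: str
    raw: Dict[str, int]
    denom: Dict[str, int]
    tpm: Dict[str, float]
    pseudo_applied: Dict[str, bool]


@dataclass
class DifferentialResult:
    mirna: str
    log2_fc: float
    p_value: float
    call: str                       # up | down | ns
    library_specific: Optional[str] = None  # "WA-only" | "WB-only"
    rpm: Dict[str, float] = field(default_factory=dict)
    raw: Dict[str, int] = field(default_factory=dict)
    q_value: Optional[float] = None


def normalize(raw_count: int, total_clean: int, pseudo: float = 0.01) -> float:
    """Reads-per-million; a zero count becomes the pseudo-expression."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    if raw_count == 0:
        return pseudo
    return raw_count / total_clean * 1e6


def log2_fold_change(expr_wa: float, expr_wb: float) -> float:
    if expr_wa <= 0 or expr_wb <= 0:
        raise ValueError("expressions must be positive (apply the pseudo first)")
    return math.log2(expr_wa / expr_wb)


def count_test_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library 1) vs y (library 2).

    With t = n2/n1 the conditional law of Y given x is negative binomial:
    P(Y=y|x) = t^y (x+y)! / (x! y! (1+t)^(x+y+1)).  Both tails are computed
    through the regularised incomplete beta function (exact NB tail identity,
    stable in the far tails); the doubled smaller tail is capped at 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    t = n2 / n1
    p_success = 1.0 / (1.0 + t)          # NB(r=x+1, p) with support on y
    lower = float(betainc(x + 1, y + 1, p_success))       # P(Y <= y)
    upper = 1.0 if y == 0 else float(betainc(y, x + 1, 1.0 - p_success))  # P(Y >= y)
    return min(1.0, 2.0 * min(lower, upper))


def fisher_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 count table (alternative)."""
    return float(fisher_exact([[x, n1 - x], [y, n2 - y]])[1])


def normalized_expression(mirna: str, raw: Dict[str, int], denom: Dict[str, int],
                          pseudo: float = 0.01) -> NormalizedExpression:
    tpm, flag = {}, {}
    for lib, c in raw.items():
        tpm[lib] = normalize(c, denom[lib], pseudo)
        flag[lib] = c == 0
    return NormalizedExpression(mirna, dict(raw), dict(denom), tpm, flag)


def call_de(counts: Sequence[Tuple[str, int, int]], denoms: Tuple[int, int],
            cfg: DEConfig = DEConfig(),
            libraries: Tuple[str, str] = ("WA", "WB")) -> List[DifferentialResult]:
    """Run normalisation, fold change, test and thresholding per miRNA.

    ``counts`` rows are (mirna, count_lib1, count_lib2); ``denoms`` the two
    libraries' total clean reads.
    """
    la, lb = libraries
    n1, n2 = denoms
    test = count_test_p if cfg.test == "audic_claverie" else fisher_p
    results = []
    for mirna, x, y in counts:
        ea = normalize(x, n1, cfg.pseudo)
        eb = normalize(y, n2, cfg.pseudo)
        fc = log2_fold_change(ea, eb)
        p = test(x, y, n1, n2)
        if p <= cfg.alpha and fc >= cfg.fc_threshold:
            call = "up"
        elif p <= cfg.alpha and fc <= -cfg.fc_threshold:
            call = "down"
        else:
            call = "ns"
        specific = None
        if x == 0 and y > 0:
            specific = f"{lb}-only"
        elif y == 0 and x > 0:
            specific = f"{la}-only"
        results.append(DifferentialResult(
            mirna=mirna, log2_fc=fc, p_value=p, call=call,
            library_specific=specific, rpm={la: ea, lb: eb},
            raw={la: x, lb: y}))
    if results and cfg.adjust == "BH":
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def de_frame(results: List[DifferentialResult],
             libraries: Tuple[str, str] = ("WA", "WB")) -> pd.DataFrame:
    la, lb = libraries
    rows = [{
        "mirna": r.mirna,
        f"count_{la}": r.raw.get(la), f"count_{lb}": r.raw.get(lb),
        f"rpm_{la}": round(r.rpm.get(la, float("nan")), 4),
        f"rpm_{lb}": round(r.rpm.get(lb, float("nan")), 4),
        "log2_fc": round(r.log2_fc, 2), "p_value": r.p_value,
        "q_value": r.q_value, "call": r.call,
        "specificity": r.library_specific or "",
    } for r in results]
    return pd.DataFrame(rows)
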