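"""Diagnostic concordance statistics between two MSI assays.

Operates on 2x2 contingency tables with the index method on rows and the
comparator (gold standard) on columns, positive category first:

                    comparator +   comparator -
    index method +       a              b
    index method -       c              d
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .calls import SampleCall


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def cohen_kappa(table: ContingencyTable2x2) -> float:
    """Chance-corrected agreement (Po - Pe) / (1 - Pe).

    When the chance agreement Pe is 1 (all mass in one marginal cell) the
    statistic is defined as 1: the raters cannot disagree.
    """
    n = table.total
    po = (table.a + table.d) / n
    pe = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / (n * n)
    if pe >= 1.0 - 1e-15:
        return 1.0
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Standard screening metrics, in percent; None where the defining
    margin is zero (the metric is undefined, not 0)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    prevalence: float


def _ratio_percent(num: int, den: int) -> Optional[float]:
    if den == 0:
        return None
    return 100.0 * num / den


def diagnostic_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and prevalence with the gold
    standard on columns."""
    return DiagnosticMetrics(
        sensitivity=_ratio_percent(table.a, table.a + table.c),
        specificity=_ratio_percent(table.d, table.b + table.d),
        ppv=_ratio_percent(table.a, table.a + table.b),
        npv=_ratio_percent(table.d, table.c + table.d),
        prevalence=100.0 * (table.a + table.c) / table.total,
    )


def table_from_calls(
    index_positive: Sequence[bool], comparator_positive: Sequence[bool]
) -> ContingencyTable2x2:
    """Cross-tabulate paired binary outcomes (pairs with a missing /
    non-contributory value must be excluded by the caller beforehand)."""
    if len(index_positive) != len(comparator_positive):
        raise ValueError("paired outcome vectors differ in length")
    a = b = c = d = 0
    for idx, comp in zip(index_positive, comparator_positive):
        if idx and comp:
            a += 1
        elif idx:
            b += 1
        elif comp:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def calls_to_frame(calls: Sequence[SampleCall]) -> pd.DataFrame:
    """Flatten sample calls to one row per locus (plus the sample verdict)."""
    rows = []
    for call in calls:
        for locus_call in call.per_locus:
            rows.append(
                {
                    "sample": call.sample,
                    "sample_status": call.status,
                    "locus": locus_call.locus,
                    "locus_status": locus_call.status,
                    "n_reads": locus_call.n_reads,
                    "unstable_proportion": round(
                        sum(p for _s, p in locus_call.unstable_components), 6
                    ),
                    "mean_shifts": ";".join(
                        f"{s:+.2f}" for s, _p in locus_call.unstable_components
                    ),
                    "lrt_p": (
                        f"{locus_call.lrt_p:.3e}" if locus_call.lrt_p is not None else ""
                    ),
                    "power": (
                        f"{locus_call.power:.3f}" if locus_call.power is not None else ""
                    ),
                    "polymorphism_suspected": locus_call.polymorphism_suspected,
                }
            )
    columns = [
        "sample",
        "sample_status",
        "locus",
        "locus_status",
        "n_reads",
        "unstable_proportion",
        "mean_shifts",
        "lrt_p",
        "power",
        "polymorphism_suspected",
    ]
    return pd.DataFrame(rows, columns=columns)


def render_report(
    calls: Sequence[SampleCall],
    tables: Optional[dict[str, ContingencyTable2x2]] = None,
    metadata: Optional[dict[str, object]] = None,
) -> tuple[str, str]:
    """Deterministic (TSV, text) report of sample calls and optional
    concordance tables; ``metadata`` (seeds, thresholds, versions) is
    echoed verbatim into the text report."""
    from . import __version__

    frame = calls_to_frame(calls)
    tsv = frame.to_csv(sep="\t", index=False)
    lines = [f"msicall {__version__} report"]
    for key in sorted(metadata or {}):
        lines.append(f"  {key}: {metadata[key]}")
    lines.append("")
    counts = frame.drop_duplicates("sample")["sample_status"].value_counts().to_dict()
    lines.append(
        "samples: "
        + ", ".join(f"{status}={counts.get(status, 0)}" for status in ("MSI", "MSS", "non_contributory"))
    )
    for name, table in sorted((tables or {}).items()):
        metrics = diagnostic_metrics(table)
        kappa = cohen_kappa(table)

        def fmt(value: Optional[float]) -> str:
            return "NA" if value is None else f"{value:.1f}%"

        lines.append(
            f"{name}: [[{table.a}, {table.b}], [{table.c}, {table.d}]] "
            f"kappa={kappa:.3f} sens={fmt(metrics.sensitivity)} "
            f"spec={fmt(metrics.specificity)} ppv={fmt(metrics.ppv)} "
            f"npv={fmt(metrics.npv)} prev={metrics.prevalence:.1f}%"
        )
    return tsv, "\n".join(lines) + "\n"
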