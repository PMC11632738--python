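"""Paired agreement analysis: caliper reference vs automated measurements.

For each of the nine measurements the conventional caliper value (CM) is
compared with the automated value from each program version (AM1: 200
training epochs, AM2: 1000 epochs) on the same subjects.  Differences are
oriented CM - AM; agreement is tested with a two-sided paired t-test
(t = mean_d / (sd_d / sqrt(n)), df = n - 1) with no multiple-testing
correction, and significance is flagged at both the 5% and 1% levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .measurements import MEASUREMENT_IDS, MeasurementVector


class PairingError(ValueError):
    """Subject ids do not align across methods."""


@dataclass
class PairedSeries:
    measurement_id: str
    reference: np.ndarray  # mm, ordered by subject
    automated: np.ndarray  # mm, same subject order

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        self.automated = np.asarray(self.automated, dtype=np.float64)
        if self.reference.shape != self.automated.shape:
            raise PairingError("reference/automated lengths differ")
        if self.n < 2:
            raise PairingError("need at least 2 paired subjects")

    @property
    def n(self) -> int:
        return int(self.reference.size)

    @property
    def differences(self) -> np.ndarray:
        return self.reference - self.automated


def paired_differences(series: PairedSeries) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of reference - automated."""
    d = series.differences
    return float(d.mean()), float(d.std(ddof=1))


def paired_t_test(mean_d: float, sd_d: float, n: int) -> tuple[float, int, float]:
    """Two-sided paired t-test from summary statistics.

    Degenerate sd_d = 0 uses the convention p = 1 for a zero mean
    difference and p = 0 (infinite t) otherwise.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    if sd_d == 0:
        if mean_d == 0:
            return 0.0, df, 1.0
        return float(np.sign(mean_d) * np.inf), df, 0.0
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


@dataclass
class AgreementRow:
    measurement_id: str
    version: str            # "AM1" | "AM2"
    n: int
    ref_mean: float
    ref_sd: float
    am_mean: float
    am_sd: float
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float
    significant_05: bool
    significant_01: bool


@dataclass
class AgreementReport:
    rows: list[AgreementRow]

    def row(self, measurement_id: str, version: str) -> AgreementRow:
        for r in self.rows:
            if r.measurement_id == measurement_id and r.version == version:
                return r
        raise KeyError((measurement_id, version))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")

    def format_tables(self) -> str:
        """Human-readable mirror of the published table layout."""
        versions = sorted({r.version for r in self.rows})
        header = "Measurement  ref mean±SD "
        for v in versions:
            header += f"  {v} mean±SD   diff mean±SD  p({v[-1]})"
        lines = [header]
        for mid in MEASUREMENT_IDS:
            rows = [r for r in self.rows if r.measurement_id == mid]
            if not rows:
                continue
            line = f"{mid:<11s}  {rows[0].ref_mean:5.2f}±{rows[0].ref_sd:4.2f}"
            for r in rows:
                line += (
                    f"  {r.am_mean:5.2f}±{r.am_sd:4.2f}  "
                    f"{r.mean_diff:6.2f}±{r.sd_diff:4.2f}  {_fmt_p(r.p):<8s}"
                )
            lines.append(line)
        return "\n".join(lines)


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _aligned(
    ref: list[MeasurementVector], am: list[MeasurementVector], mid: str
) -> PairedSeries:
    ref_by_id = {v.subject_id: v for v in ref}
    am_by_id = {v.subject_id: v for v in am}
    if set(ref_by_id) != set(am_by_id):
        raise PairingError(
            "subject ids differ between methods: "
            f"{sorted(set(ref_by_id) ^ set(am_by_id))[:5]}"
        )
    ids = sorted(ref_by_id)
    return PairedSeries(
        mid,
        np.array([ref_by_id[i].values[mid] for i in ids]),
        np.array([am_by_id[i].values[mid] for i in ids]),
    )


def build_report(
    cm: list[MeasurementVector],
    am1: list[MeasurementVector] | None = None,
    am2: list[MeasurementVector] | None = None,
) -> AgreementReport:
    """Assemble the full agreement report over both program versions.

    Either automated column may be omitted (single-version comparison);
    at least one is required.
    """
    versions = [("AM1", am1), ("AM2", am2)]
    if all(v is None for _, v in versions):
        raise ValueError("at least one automated measurement set is required")
    rows: list[AgreementRow] = []
    for mid in MEASUREMENT_IDS:
        for tag, am in versions:
            if am is None:
                continue
            series = _aligned(cm, am, mid)
            mean_d, sd_d = paired_differences(series)
            t, df, p = paired_t_test(mean_d, sd_d, series.n)
            rows.append(
                AgreementRow(
                    measurement_id=mid,
                    version=tag,
                    n=series.n,
                    ref_mean=float(series.reference.mean()),
                    ref_sd=float(series.reference.std(ddof=1)),
                    am_mean=float(series.automated.mean()),
                    am_sd=float(series.automated.std(ddof=1)),
                    mean_diff=mean_d,
                    sd_diff=sd_d,
                    t=t,
                    df=df,
                    p=p,
                    significant_05=p < 0.05,
                    significant_01=p < 0.01,
                )
            )
    return AgreementReport(rows)


def count_significant(
    report: AgreementReport, alpha: float = 0.01, require_both: bool = True
) -> int:
    """Measurements discrepant at ``alpha`` in both (or either) version."""
    count = 0
    versions = sorted({r.version for r in report.rows})
    for mid in MEASUREMENT_IDS:
        flags = [report.row(mid, v).p < alpha for v in versions
                 if any(r.measurement_id == mid and r.version == v for r in report.rows)]
        if not flags:
            continue
        hit = all(flags) if require_both else any(flags)
        if hit:
            count += 1
    return count


def report_from_summary(
    diff_stats: dict[str, dict[str, tuple[float, float]]],
    group_stats: dict[str, dict[str, tuple[float, float]]] | None = None,
    n: int = 20,
) -> AgreementReport:
    """Rebuild the report from published summary statistics.

    ``diff_stats[mid][version] = (mean_diff, sd_diff)``; group means/SDs are
    optional context columns.  Used to re-derive every t and p from printed
    mean±SD values.
    """
    rows: list[AgreementRow] = []
    for mid in MEASUREMENT_IDS:
        for tag in ("AM1", "AM2"):
            if mid not in diff_stats or tag not in diff_stats[mid]:
                continue
            mean_d, sd_d = diff_stats[mid][tag]
            t, df, p = paired_t_test(mean_d, sd_d, n)
            g = group_stats.get(mid, {}) if group_stats else {}
            ref_mean, ref_sd = g.get("CM", (np.nan, np.nan))
            am_mean, am_sd = g.get(tag, (np.nan, np.nan))
            rows.append(
                AgreementRow(
                    measurement_id=mid, version=tag, n=n,
                    ref_mean=ref_mean, ref_sd=ref_sd,
                    am_mean=am_mean, am_sd=am_sd,
                    mean_diff=mean_d, sd_diff=sd_d,
                    t=t, df=df, p=p,
                    significant_05=p < 0.05, significant_01=p < 0.01,
                )
            )
    return AgreementReport(rows)
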