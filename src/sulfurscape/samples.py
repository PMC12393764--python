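"""Sample tables, atomic C:N / C:S / N:S ratios and collagen quality screening.

Bone-collagen isotope measurements are only interpretable when the collagen
is well preserved. The screening applies the conventional elemental and
atomic-ratio windows (collagen yield above 1 %, %C 30–44, %N 11–16,
%S 0.15–0.35, C:N 2.9–3.6, C:S 300–900, N:S 100–300, all bounds inclusive)
and, when the retained samples feed the isoscape regression, additionally
drops individuals reported as non-local and records carrying only a δ³⁴S
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# IUPAC standard atomic weights
ATOMIC_WEIGHT_C = 12.011
ATOMIC_WEIGHT_N = 14.007
ATOMIC_WEIGHT_S = 32.06

#: canonical column names of a sample table
SAMPLE_COLUMNS = (
    "sample_id", "site_id", "kind", "taxon", "period",
    "d13C", "d15N", "d34S",
    "pct_col", "pct_C", "pct_N", "pct_S",
    "cn_ratio", "cs_ratio", "ns_ratio",
    "local_status", "source",
)
NUMERIC_COLUMNS = (
    "d13C", "d15N", "d34S", "pct_col", "pct_C", "pct_N", "pct_S",
    "cn_ratio", "cs_ratio", "ns_ratio",
)
MANDATORY_COLUMNS = ("sample_id", "site_id", "kind")

D34S_PLAUSIBLE = (-30.0, 40.0)


@dataclass
class QcThresholds:
    """Retention windows for the collagen quality indicators.

    ``cs_range``/``ns_range`` are the 600 ± 300 and 200 ± 100 conventions
    written as closed intervals.
    """

    pct_col_min: float = 1.0
    pct_C_range: tuple[float, float] = (30.0, 44.0)
    pct_N_range: tuple[float, float] = (11.0, 16.0)
    pct_S_range: tuple[float, float] = (0.15, 0.35)
    cn_range: tuple[float, float] = (2.9, 3.6)
    cs_range: tuple[float, float] = (300.0, 900.0)
    ns_range: tuple[float, float] = (100.0, 300.0)

    def __post_init__(self) -> None:
        for name in ("pct_C_range", "pct_N_range", "pct_S_range",
                     "cn_range", "cs_range", "ns_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} exceeds hi {hi}")


@dataclass
class ParseReport:
    n_rows: int
    n_dropped: int
    messages: list[str] = field(default_factory=list)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_sample_table(path, schema_map: dict[str, str] | None = None,
                      ) -> tuple[pd.DataFrame, ParseReport]:
    """Read a delimited sample table into canonical columns.

    ``schema_map`` maps canonical names to the file's column names; unmapped
    canonical columns default to their own name. Missing numeric cells stay
    absent (NaN), never zero. Rows lacking a mandatory field are dropped and
    counted in the report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                      keep_default_na=True, encoding="utf-8")
    schema_map = schema_map or {}
    out = pd.DataFrame(index=raw.index)
    for canon in SAMPLE_COLUMNS:
        src = schema_map.get(canon, canon)
        out[canon] = raw[src] if src in raw.columns else pd.Series(pd.NA, index=raw.index)
    for canon in MANDATORY_COLUMNS:
        src = schema_map.get(canon, canon)
        if src not in raw.columns:
            raise ValueError(f"mandatory column {canon!r} (file column {src!r}) not found")

    messages: list[str] = []
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna() & (out[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"unparseable numeric value {out[col][row]!r} in column {col!r}, row {row}")
        out[col] = parsed

    drop = out[list(MANDATORY_COLUMNS)].isna().any(axis=1)
    if drop.any():
        messages.append(f"dropped {int(drop.sum())} rows lacking mandatory fields")
    out = out[~drop].reset_index(drop=True)

    dup = out["sample_id"][out["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id: {dup.iloc[0]!r}")

    present = out["d34S"].notna()
    implausible = present & ~out["d34S"].between(*D34S_PLAUSIBLE)
    if implausible.any():
        sid = out.loc[implausible, "sample_id"].iloc[0]
        raise ValueError(f"d34S outside plausible range [-30, 40] for sample {sid!r}")
    for col in ("pct_col", "pct_C", "pct_N", "pct_S"):
        neg = out[col].notna() & (out[col] < 0)
        if neg.any():
            sid = out.loc[neg, "sample_id"].iloc[0]
            raise ValueError(f"negative {col} for sample {sid!r}")

    report = ParseReport(n_rows=len(out), n_dropped=int(drop.sum()), messages=messages)
    return out, report


def atomic_ratios(pct_C=np.nan, pct_N=np.nan, pct_S=np.nan):
    """Atomic C:N, C:S and N:S ratios from elemental weight percentages.

    Weight fractions are converted to mole ratios with the standard atomic
    weights; a ratio whose denominator is absent or zero comes back NaN.
    Works on scalars or arrays.
    """
    c = np.asarray(pct_C, dtype=float)
    n = np.asarray(pct_N, dtype=float)
    s = np.asarray(pct_S, dtype=float)
    for name, arr in (("pct_C", c), ("pct_N", n), ("pct_S", s)):
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError(f"negative {name}")
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.where(n > 0, (c / n) * (ATOMIC_WEIGHT_N / ATOMIC_WEIGHT_C), np.nan)
        cs = np.where(s > 0, (c / s) * (ATOMIC_WEIGHT_S / ATOMIC_WEIGHT_C), np.nan)
        ns = np.where(s > 0, (n / s) * (ATOMIC_WEIGHT_S / ATOMIC_WEIGHT_N), np.nan)
    if np.ndim(pct_C) == 0 and np.ndim(pct_N) == 0 and np.ndim(pct_S) == 0:
        return float(cn), float(cs), float(ns)
    return cn, cs, ns


def _effective_ratios(df: pd.DataFrame) -> pd.DataFrame:
    """Lab-reported ratios where present, recomputed from percentages otherwise."""
    cn, cs, ns = atomic_ratios(df["pct_C"].to_numpy(), df["pct_N"].to_numpy(),
                               df["pct_S"].to_numpy())
    eff = pd.DataFrame({
        "cn": df["cn_ratio"].fillna(pd.Series(cn, index=df.index)),
        "cs": df["cs_ratio"].fillna(pd.Series(cs, index=df.index)),
        "ns": df["ns_ratio"].fillna(pd.Series(ns, index=df.index)),
    }, index=df.index)
    return eff


def qc_screen(samples: pd.DataFrame, thresholds: QcThresholds | None = None,
              purpose: str = "diet_stats") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a sample table into retained and excluded sets.

    A sample is retained iff every *available* quality metric lies inside
    its window (missing metrics do not veto). For ``purpose="isoscape"``
    the screen additionally drops published non-locals, sulfur-only
    records, and samples with no sulfur-bearing QC information at all.

    Returns (retained, excluded); ``excluded`` carries a ``reasons`` column
    of semicolon-joined machine-readable codes.
    """
    if purpose not in ("isoscape", "diet_stats"):
        raise ValueError(f"unknown purpose {purpose!r}")
    thresholds = thresholds or QcThresholds()
    df = samples.reset_index(drop=True)
    eff = _effective_ratios(df)

    def outside(series, lo, hi):
        return series.notna() & ~series.between(lo, hi)

    reasons = pd.Series([[] for _ in range(len(df))], index=df.index, dtype=object)

    def add(mask, code):
        for i in df.index[mask]:
            reasons[i].append(code)

    add(df["pct_col"].notna() & (df["pct_col"] < thresholds.pct_col_min),
        "pct_col below minimum")
    for col, rng, label in (
        ("pct_C", thresholds.pct_C_range, "pct_C"),
        ("pct_N", thresholds.pct_N_range, "pct_N"),
        ("pct_S", thresholds.pct_S_range, "pct_S"),
    ):
        add(outside(df[col], *rng), f"{label} outside range")
    for key, rng, label in (
        ("cn", thresholds.cn_range, "C:N"),
        ("cs", thresholds.cs_range, "C:S"),
        ("ns", thresholds.ns_range, "N:S"),
    ):
        lo, hi = rng
        add(eff[key].notna() & (eff[key] < lo), f"{label} below range")
        add(eff[key].notna() & (eff[key] > hi), f"{label} above range")

    if purpose == "isoscape":
        add(df["local_status"] == "nonlocal", "non-local")
        sulfur_only = df["d34S"].notna() & df["d13C"].isna() & df["d15N"].isna()
        add(sulfur_only, "sulfur-only record")
        no_s_qc = df["pct_S"].isna() & eff["cs"].isna() & eff["ns"].isna()
        add(no_s_qc, "no sulfur QC metrics")

    excluded_mask = reasons.map(len) > 0
    retained = df[~excluded_mask].copy()
    excluded = df[excluded_mask].copy()
    excluded["reasons"] = reasons[excluded_mask].map("; ".join)
    return retained, excluded


def exclusion_counts(excluded: pd.DataFrame) -> pd.Series:
    """Number of excluded samples carrying each reason code."""
    if excluded.empty:
        return pd.Series(dtype=int, name="n")
    codes = excluded["reasons"].str.split("; ").explode()
    counts = codes.value_counts()
    counts.name = "n"
    return counts


def write_screen_report(retained: pd.DataFrame, excluded: pd.DataFrame, path) -> None:
    """Write a per-sample screening report plus per-reason counts.

    The main file lists every input sample with its status and reasons; a
    sibling ``<stem>_counts`` file tallies exclusions by reason.
    """
    path = Path(path)
    rows = [{"sample_id": s, "status": "retained", "reasons": ""}
            for s in retained["sample_id"]]
    rows += [{"sample_id": s, "status": "excluded", "reasons": r}
             for s, r in zip(excluded["sample_id"], excluded["reasons"])]
    pd.DataFrame(rows, columns=["sample_id", "status", "reasons"]).to_csv(
        path, index=False, sep=_sep_for(path))
    counts = exclusion_counts(excluded)
    counts_path = path.with_name(path.stem + "_counts" + path.suffix)
    counts.rename_axis("reason").reset_index().to_csv(
        counts_path, index=False, sep=_sep_for(path))


def read_screen_report(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    return df
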