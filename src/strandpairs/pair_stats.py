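"""Pairing-ratio statistics and dataset-level summaries for strand pairs.

Per pair the ratios are

    R    = 100 * PL / EL      common part over the whole pairing length,
    Rt_i = 100 * PL / SL_i    common part over each strand length,

all carried on the 0-100 percent scale, and the alignment rule

    R >= 25  and  Rt1 >= 40  and  Rt2 >= 40      (boundaries inclusive)

which nearly all native strand pairs satisfy and which bounds the register
offsets worth scoring in strand-alignment prediction.

Dataset summaries mirror the standard reporting layout: a cross-table of
|SL1 - SL2| against which terminal extensions exist, a min/max/mean/sd
summary per variable, ratio histograms on right-closed percent bins, and
cumulative curves CP(x) = percent of pairs with ratio >= x.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from strandpairs.pair_geometry import StrandPair

RATIO_VARIABLES = ("R", "Rt1", "Rt2")
LENGTH_VARIABLES = ("SL1", "SL2", "PL", "Et1", "Et2", "EL")

#: Alignment-rule thresholds, percent.
RULE_MIN_R = 25.0
RULE_MIN_RT = 40.0


@dataclass(frozen=True)
class PairStats:
    """The ratio statistics and rule verdict of one strand pair."""

    R: float
    Rt1: float
    Rt2: float
    rule_pass: bool


def round2(x: float) -> float:
    """Round half-up to two decimals — display convention for percent
    tables (banker's rounding would print 0.125 as 0.12, tables print 0.13)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def pairing_ratio(pair: StrandPair) -> float:
    """R = 100 * PL / EL = 100 * PL / (PL + Et1 + Et2)."""
    return 100.0 * pair.PL / pair.EL


def strand_ratios(pair: StrandPair) -> tuple[float, float]:
    """Rt_i = 100 * PL / SL_i for i = 1, 2."""
    return 100.0 * pair.PL / pair.SL1, 100.0 * pair.PL / pair.SL2


def check_rule(stats: PairStats) -> bool:
    """True iff R >= 25 and Rt1 >= 40 and Rt2 >= 40, boundaries included."""
    return (
        stats.R >= RULE_MIN_R
        and stats.Rt1 >= RULE_MIN_RT
        and stats.Rt2 >= RULE_MIN_RT
    )


def pair_statistics(pair: StrandPair) -> PairStats:
    """Compute R, Rt1, Rt2 and the rule verdict for one pair."""
    r = pairing_ratio(pair)
    rt1, rt2 = strand_ratios(pair)
    stats = PairStats(R=r, Rt1=rt1, Rt2=rt2, rule_pass=False)
    return PairStats(R=r, Rt1=rt1, Rt2=rt2, rule_pass=check_rule(stats))


def select_pairs(
    pairs: Iterable[StrandPair],
    include_bulged: bool = False,
    include_interchain: bool = True,
) -> list[StrandPair]:
    """Apply the default inclusion policy: beta-bulged pairs are excluded
    (their residue pairing is locally broken, so the registration is not a
    clean block), interchain pairs are included."""
    out = []
    for p in pairs:
        if p.bulged and not include_bulged:
            continue
        if p.interchain and not include_interchain:
            continue
        out.append(p)
    return out


def pair_frame(pairs: Sequence[StrandPair]) -> pd.DataFrame:
    """Per-pair table of lengths, ratios and the rule verdict."""
    rows = []
    for p in pairs:
        st = pair_statistics(p)
        rows.append(
            {
                "chain1": p.strand1.chain_id,
                "chain2": p.strand2.chain_id,
                "sheet": p.sheet_label,
                "strand1": p.strand1.strand_ordinal,
                "strand2": p.strand2.strand_ordinal,
                "orientation": p.orientation,
                "SL1": p.SL1,
                "SL2": p.SL2,
                "PL": p.PL,
                "Et1": p.Et1,
                "Et2": p.Et2,
                "EL": p.EL,
                "bulged": p.bulged,
                "interchain": p.interchain,
                "R": st.R,
                "Rt1": st.Rt1,
                "Rt2": st.Rt2,
                "rule_pass": st.rule_pass,
            }
        )
    columns = [
        "chain1", "chain2", "sheet", "strand1", "strand2", "orientation",
        "SL1", "SL2", "PL", "Et1", "Et2", "EL", "bulged", "interchain",
        "R", "Rt1", "Rt2", "rule_pass",
    ]
    return pd.DataFrame(rows, columns=columns)


DIFF_BINS = [str(d) for d in range(11)] + [">10"]
_CASE_COLUMNS = [
    "pct_Et1=0_Et2=0",
    "pct_Et1=0_Et2>0",
    "pct_Et1>0_Et2=0",
    "pct_Et1>0_Et2>0",
]


def length_difference_table(pairs: Sequence[StrandPair]) -> pd.DataFrame:
    """Cross-table of |SL1 - SL2| (rows 0..10 and '>10') against which
    terminal extensions exist.

    Columns: pair count, percent of the grand total, and — within each
    row — the percent of pairs in each of the four extension-existence
    cases.  Structural zeros are guaranteed by the registration identities:
    equal lengths force Et1 = Et2 (single-extension cells are 0 in row 0),
    and unequal lengths force at least one extension (the both-zero cell is
    0 in every other row).  An empty input yields a table of zero counts.
    """
    idx = pd.Index(DIFF_BINS, name="abs_SL1-SL2")
    counts = pd.Series(0, index=idx, dtype=int)
    case_counts = pd.DataFrame(0, index=idx, columns=_CASE_COLUMNS, dtype=int)
    for p in pairs:
        d = abs(p.SL1 - p.SL2)
        row = str(d) if d <= 10 else ">10"
        counts[row] += 1
        case = (
            _CASE_COLUMNS[0] if (p.Et1 == 0 and p.Et2 == 0)
            else _CASE_COLUMNS[1] if p.Et1 == 0
            else _CASE_COLUMNS[2] if p.Et2 == 0
            else _CASE_COLUMNS[3]
        )
        case_counts.loc[row, case] += 1
    total = counts.sum()
    table = pd.DataFrame(index=idx)
    table["count"] = counts
    table["percent"] = 100.0 * counts / total if total else 0.0
    for col in _CASE_COLUMNS:
        with np.errstate(invalid="ignore"):
            table[col] = np.where(
                counts > 0, 100.0 * case_counts[col] / counts.replace(0, 1), 0.0
            )
    return table


def variable_summary(pairs: Sequence[StrandPair]) -> pd.DataFrame:
    """Min, max, mean and standard deviation of SL1, SL2, PL, Et1, Et2, EL.

    The sd uses the sample (n-1) convention.  By linearity of the mean the
    identity mean(EL) = mean(PL) + mean(Et1) + mean(Et2) holds exactly
    before rounding.
    """
    if not len(pairs):
        raise ValueError("no pairs: variable summary undefined on empty input")
    data = {v: np.array([getattr(p, v) for p in pairs]) for v in LENGTH_VARIABLES}
    rows = {
        v: {
            "min": int(a.min()),
            "max": int(a.max()),
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        }
        for v, a in data.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[["min", "max", "mean", "sd"]]


def _ratio_values(pairs: Sequence[StrandPair], variable: str) -> np.ndarray:
    if variable not in RATIO_VARIABLES:
        raise ValueError(f"unknown ratio variable {variable!r}")
    stats = [pair_statistics(p) for p in pairs]
    return np.array([getattr(s, variable) for s in stats], dtype=float)


def distribution(
    pairs: Sequence[StrandPair], variable: str, bin_width: float = 5.0
) -> pd.DataFrame:
    """Histogram of a ratio variable over right-closed bins of (0, 100].

    Bins are (0, w], (w, 2w], ..., (100-w, 100]; pairs at exactly 100%
    (no terminal extensions) fall in the top bin.  Values are percents of
    all pairs and sum to 100 up to floating rounding.
    """
    if not (0 < bin_width <= 100) or abs(100 / bin_width - round(100 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 100")
    values = _ratio_values(pairs, variable)
    nbins = int(round(100 / bin_width))
    edges = np.linspace(0, 100, nbins + 1)
    # right-closed: count v in (lo, hi]
    if len(values):
        which = np.ceil(values / bin_width).astype(int) - 1
        which = np.clip(which, 0, nbins - 1)
        counts = np.bincount(which, minlength=nbins)
        percent = 100.0 * counts / len(values)
    else:
        counts = np.zeros(nbins, dtype=int)
        percent = np.zeros(nbins)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "percent": percent,
        }
    )


def cumulative_curve(
    pairs: Sequence[StrandPair],
    variable: str,
    grid: Sequence[float] | None = None,
) -> list[tuple[float, float]]:
    """Cumulative percent CP(x) = 100 * |{pairs : variable >= x}| / |pairs|
    on a percent grid (default 0, 5, ..., 100).

    CP is non-increasing and CP(0) = 100 since ratios are strictly
    positive.
    """
    if grid is None:
        grid = np.arange(0.0, 100.1, 5.0)
    values = _ratio_values(pairs, variable)
    out = []
    n = len(values)
    for x in grid:
        cp = 100.0 * float((values >= x).sum()) / n if n else 0.0
        out.append((float(x), cp))
    return out


@dataclass
class DatasetSummary:
    """All dataset-level summaries for one set of strand pairs."""

    n_pairs: int
    diff_table: pd.DataFrame
    var_summary: pd.DataFrame
    histograms: dict[str, pd.DataFrame]
    cumulative: dict[str, list[tuple[float, float]]]
    rule_pass_percent: float


def summarize(
    pairs: Sequence[StrandPair],
    bin_width: float = 5.0,
    grid_step: float = 5.0,
) -> DatasetSummary:
    """Compute the full dataset summary for an already-selected pair set
    (see :func:`select_pairs` for the bulge/interchain policy)."""
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)
    stats = [pair_statistics(p) for p in pairs]
    n = len(pairs)
    rule_pct = 100.0 * sum(s.rule_pass for s in stats) / n if n else 0.0
    return DatasetSummary(
        n_pairs=n,
        diff_table=length_difference_table(pairs),
        var_summary=variable_summary(pairs) if n else None,
        histograms={v: distribution(pairs, v, bin_width) for v in RATIO_VARIABLES},
        cumulative={v: cumulative_curve(pairs, v, grid) for v in RATIO_VARIABLES},
        rule_pass_percent=rule_pct,
    )


def format_diff_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display form of the cross-table: percents rounded half-up to two
    decimals, counts left as integers."""
    out = table.copy()
    for col in out.columns:
        if col != "count":
            out[col] = out[col].map(round2)
    return out


def format_var_summary(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["mean"] = out["mean"].map(round2)
    out["sd"] = out["sd"].map(round2)
    return out
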