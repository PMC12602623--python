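"""Performance classification against Bradley-style robustness bands.

Rejection rates under a true null are graded against Bradley's criteria at
nominal alpha: *stringent* [0.9a, 1.1a] and *liberal* [0.5a, 1.5a]; rates
below the liberal band are *overly conservative*, above it *overly liberal*.
Coverage of a 95% CI is graded analogously: stringent [.945, .955], liberal
[.925, .975], with too-low coverage meaning intervals are *too narrow* and
too-high meaning *too broad*.  All band edges are inclusive of the tighter
class.

``guidance_tables`` condenses a full grid run into the practitioner-facing
matrices: per (heteroskedasticity source, assumption cell, n), which methods
hold which class.  Cells collapse "heteroskedastic" over g in {0.5, 1, 2}
and "non-normal" over the moderate and severe shapes; a method is listed at
the worst class it attains across the collapsed sub-scenarios, so a listing
guarantees the class over the whole cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CriterionBands",
    "classify_type1",
    "classify_coverage",
    "classify_power",
    "guidance_tables",
]


@dataclass(frozen=True)
class CriterionBands:
    alpha: float = 0.05
    stringent_cov: tuple[float, float] = (0.945, 0.955)
    liberal_cov: tuple[float, float] = (0.925, 0.975)
    power_good: float = 0.80
    power_strong: float = 0.90

    @property
    def stringent_t1(self) -> tuple[float, float]:
        return (0.9 * self.alpha, 1.1 * self.alpha)

    @property
    def liberal_t1(self) -> tuple[float, float]:
        return (0.5 * self.alpha, 1.5 * self.alpha)


#: Ordering from best to worst, used for worst-class-wins aggregation.
_T1_ORDER = ("stringent", "liberal", "overly_conservative", "overly_liberal")
_COV_ORDER = ("stringent", "liberal", "too_narrow", "too_broad")
_POWER_ORDER = ("strong", "good", "underpowered")


def _check_rate(rate: float) -> None:
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate!r} outside [0, 1]")


_EDGE_TOL = 1e-12  # band edges are inclusive; guard float noise in 0.9*alpha


def _inside(rate: float, band: tuple[float, float]) -> bool:
    return band[0] - _EDGE_TOL <= rate <= band[1] + _EDGE_TOL


def classify_type1(rate: float, bands: CriterionBands = CriterionBands()) -> str:
    """Grade a null rejection rate against the Bradley bands (edges inclusive)."""
    _check_rate(rate)
    if _inside(rate, bands.stringent_t1):
        return "stringent"
    if _inside(rate, bands.liberal_t1):
        return "liberal"
    return "overly_conservative" if rate < bands.liberal_t1[0] else "overly_liberal"


def classify_coverage(rate: float, bands: CriterionBands = CriterionBands()) -> str:
    """Grade a CI coverage rate; low coverage = too-narrow intervals."""
    _check_rate(rate)
    if _inside(rate, bands.stringent_cov):
        return "stringent"
    if _inside(rate, bands.liberal_cov):
        return "liberal"
    return "too_narrow" if rate < bands.liberal_cov[0] else "too_broad"


def classify_power(rate: float, bands: CriterionBands = CriterionBands()) -> str:
    _check_rate(rate)
    if rate >= bands.power_strong:
        return "strong"
    if rate >= bands.power_good:
        return "good"
    return "underpowered"


def _cell_labels(df: pd.DataFrame) -> pd.Series:
    homo = df["g"] == 0
    normal = df["distribution"] == "normal"
    labels = pd.Series(index=df.index, dtype=object)
    labels[homo & normal] = "homoskedastic & normal"
    labels[homo & ~normal] = "homoskedastic & non-normal"
    labels[~homo & normal] = "heteroskedastic & normal"
    labels[~homo & ~normal] = "heteroskedastic & non-normal"
    return labels


def _worst(classes: pd.Series, order: tuple[str, ...]) -> str:
    ranks = classes.map(order.index)
    return order[int(ranks.max())]


def guidance_tables(
    summaries: pd.DataFrame, bands: CriterionBands = CriterionBands()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the two method-guidance matrices from a tidy grid table.

    Returns ``(validity, power)``: the validity table grades null models by
    type-I error and effect models by coverage (worst of the two, where both
    apply to a method); the power table grades effect models by rejection
    rate.  Rows are (het source block, assumption cell, n); the cell entry
    is each method's worst class over the collapsed sub-scenarios.
    """
    df = summaries.copy()
    df["block"] = df["model"].map(
        {1: "het ~ predictor of interest", 2: "het ~ predictor of interest",
         3: "het ~ other predictor", 4: "het ~ other predictor"}
    )
    df["cell"] = _cell_labels(df)

    null_df = df[df["model"].isin([1, 3])].copy()
    eff_df = df[df["model"].isin([2, 4])].copy()

    rows_v, rows_p = [], []
    keys = ["block", "cell", "n"]
    for key, grp in df.groupby(keys):
        entry_v, entry_p = {}, {}
        for method, mg in grp.groupby("method"):
            classes = []
            nulls = mg[mg["model"].isin([1, 3])]
            if not nulls.empty:
                t1 = nulls["rejection_rate"].map(
                    lambda r: classify_type1(r, bands)
                )
                classes.append(_worst(t1, _T1_ORDER))
            effs = mg[mg["model"].isin([2, 4])].dropna(subset=["coverage_rate"])
            if not effs.empty:
                cv = effs["coverage_rate"].map(
                    lambda r: classify_coverage(r, bands)
                )
                # map coverage classes onto the type-I vocabulary for a
                # single validity grade per method
                remap = {"stringent": "stringent", "liberal": "liberal",
                         "too_narrow": "overly_liberal",
                         "too_broad": "overly_conservative"}
                classes.append(remap[_worst(cv, _COV_ORDER)])
            if classes:
                ranks = [_T1_ORDER.index(c) for c in classes]
                entry_v[method] = _T1_ORDER[max(ranks)]
            pw = mg[mg["model"].isin([2, 4])]
            if not pw.empty:
                pcls = pw["rejection_rate"].map(
                    lambda r: classify_power(r, bands)
                )
                entry_p[method] = _worst(pcls, _POWER_ORDER)
        base = dict(zip(keys, key))
        rows_v.append({**base, **entry_v})
        rows_p.append({**base, **entry_p})

    validity = pd.DataFrame(rows_v).sort_values(keys).reset_index(drop=True)
    power = pd.DataFrame(rows_p).sort_values(keys).reset_index(drop=True)
    return validity, power


def render_guidance(table: pd.DataFrame, tier: str = "stringent") -> str:
    """Plain-text rendering: per row, the methods achieving ``tier`` or better."""
    order = _T1_ORDER if tier in _T1_ORDER else _POWER_ORDER
    cut = order.index(tier)
    lines = []
    method_cols = [c for c in table.columns if c not in ("block", "cell", "n")]
    for _, row in table.iterrows():
        ok = [
            m for m in method_cols
            if isinstance(row[m], str) and order.index(row[m]) <= cut
        ]
        label = "all methods" if len(ok) == len(method_cols) else ", ".join(ok)
        lines.append(
            f"{row['block']} | {row['cell']} | n={row['n']}: {label or '(none)'}"
        )
    return "\n".join(lines)
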