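"""Aggregation of per-case attack geometries into group statistics.

Conventions: statistics are plain arithmetic means with the sample (n−1)
standard deviation, reported as μ (σ); σ is left blank for n = 1.  α_FL is
averaged linearly over its signed values — its distribution for
near-perpendicular attacks is scattered over the full angular range, which is
precisely why it carries little information, and circular statistics would
mask that.  Indeterminate α_FL values are dropped from the α_FL aggregate and
counted.  The pooled "all groups" row can take the Φ mean over |Φ| so that
the two attack faces (Φ ≈ +90° and Φ ≈ −90° classes) do not cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .electrophile import LigandKind
from .pipeline import PRIMARY, CaseResult

PARAMETERS = ("d", "alpha_bd", "dp", "alpha_fl", "alpha_lw", "phi_attack", "delta")
#: parameters reported in the group-statistics table
TABLE_PARAMETERS = ("alpha_bd", "alpha_fl", "alpha_lw", "phi_attack")

#: histogram bin widths: figure-granularity defaults
DEFAULT_BIN_WIDTHS = {"d": 0.1, "alpha_bd": 5.0, "phi_attack": 5.0,
                      "alpha_fl": 5.0, "alpha_lw": 5.0}

L_LIGANDS = (LigandKind.L_ASN.value, LigandKind.L_ASP.value)


@dataclass(frozen=True)
class GroupStatistics:
    label: str
    n: int
    means: Mapping[str, float]
    stds: Mapping[str, float | None]  # None when n < 2 (or < 2 determinate)
    fl_indeterminate: int = 0
    abs_mean_phi: bool = False

    def formatted(self, param: str, digits: int = 1) -> str:
        """μ (σ) string for one parameter."""
        mu = self.means.get(param)
        if mu is None or math.isnan(mu):
            return ""
        sd = self.stds.get(param)
        if sd is None:
            return f"{mu:.{digits}f}"
        return f"{mu:.{digits}f} ({sd:.{digits}f})"


@dataclass(frozen=True)
class HistogramData:
    parameter: str
    bin_edges: np.ndarray
    counts: Mapping[str, np.ndarray]  # per group label


def results_to_frame(results: Iterable[CaseResult]) -> pd.DataFrame:
    """Flatten CaseResults into a tidy per-case table."""
    rows = []
    for r in results:
        g = r.geometry
        rows.append(
            {
                "structure_id": r.entry.structure_id,
                "chain": r.entry.chain_id,
                "class": r.entry.asparaginase_class,
                "subtype": r.entry.subtype,
                "ligand_kind": r.entry.ligand_kind,
                "role": r.nucleophile_role,
                "d": g.d if g else np.nan,
                "alpha_bd": g.alpha_bd if g else np.nan,
                "dp": g.dp if g else np.nan,
                "alpha_fl": (
                    g.alpha_fl if (g and g.alpha_fl is not None) else np.nan
                ),
                "alpha_lw": g.alpha_lw if g else np.nan,
                "phi_attack": g.phi_attack if g else np.nan,
                "tau": g.tau if g else np.nan,
                "delta": g.delta if g else np.nan,
                "chirality": g.chirality if g else "",
                "swap_applied": r.swap_applied,
                "included": r.filter_status.included,
                "exclude_reasons": "; ".join(r.filter_status.reasons),
                "notes": r.entry.notes,
            }
        )
    columns = [
        "structure_id", "chain", "class", "subtype", "ligand_kind", "role",
        "d", "alpha_bd", "dp", "alpha_fl", "alpha_lw", "phi_attack", "tau",
        "delta", "chirality", "swap_applied", "included", "exclude_reasons",
        "notes",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    for col in ("swap_applied", "included"):
        frame[col] = frame[col].astype(bool)
    for col in ("d", "alpha_bd", "dp", "alpha_fl", "alpha_lw", "phi_attack",
                "tau", "delta"):
        frame[col] = pd.to_numeric(frame[col])
    return frame


def _group_stats(
    frame: pd.DataFrame,
    label: str,
    params: Sequence[str] = PARAMETERS,
    abs_mean_phi: bool = False,
) -> GroupStatistics | None:
    if frame.empty:
        return None
    means: dict[str, float] = {}
    stds: dict[str, float | None] = {}
    fl_indet = 0
    for p in params:
        vals = frame[p].to_numpy(dtype=float)
        if p == "alpha_fl":
            fl_indet = int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        if p == "phi_attack" and abs_mean_phi:
            vals = np.abs(vals)
        if vals.size == 0:
            means[p] = float("nan")
            stds[p] = None
            continue
        means[p] = float(np.mean(vals))
        stds[p] = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
    return GroupStatistics(
        label=label,
        n=len(frame),
        means=means,
        stds=stds,
        fl_indeterminate=fl_indet,
        abs_mean_phi=abs_mean_phi,
    )


def summarize(
    results: Iterable[CaseResult] | pd.DataFrame,
    by: Sequence[str] = ("class", "subtype", "role"),
    params: Sequence[str] = PARAMETERS,
    included_only: bool = True,
) -> list[GroupStatistics]:
    """Per-group μ (σ) statistics over included cases.

    ``by`` names columns of the per-case table; empty groups are omitted.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if included_only:
        frame = frame[frame["included"]]
    out: list[GroupStatistics] = []
    for key, grp in frame.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        label = "/".join(str(k) for k in key)
        gs = _group_stats(grp, label, params)
        if gs is not None:
            out.append(gs)
    return out


def class_table(
    results: Iterable[CaseResult] | pd.DataFrame,
    role: str = PRIMARY,
    ligand_kinds: Sequence[str] = L_LIGANDS,
    params: Sequence[str] = TABLE_PARAMETERS,
) -> list[GroupStatistics]:
    """The class/type summary over primary-nucleophile substrate complexes.

    Rows: class 1 type I, type II, type s, type I + II, all class 1, class 2,
    class 3, and the pooled "All" row whose Φ mean is taken over |Φ| (the two
    attack faces would otherwise cancel).  Group sizes are additive by
    construction: n(I) + n(II) = n(I+II), n(I+II) + n(s) = n(class 1).
    """
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    frame = frame[
        frame["included"]
        & (frame["role"] == role)
        & frame["ligand_kind"].isin(list(ligand_kinds))
    ]
    c1 = frame[frame["class"] == 1]
    selections = [
        ("class 1 type I", c1[c1["subtype"] == "I"], False),
        ("class 1 type II", c1[c1["subtype"] == "II"], False),
        ("class 1 type s", c1[c1["subtype"] == "s"], False),
        ("class 1 type I + II", c1[c1["subtype"].isin(["I", "II"])], False),
        ("class 1", c1, False),
        ("class 2", frame[frame["class"] == 2], False),
        ("class 3", frame[frame["class"] == 3], False),
        ("All", frame, True),
    ]
    out = []
    for label, grp, abs_phi in selections:
        gs = _group_stats(grp, label, params, abs_mean_phi=abs_phi)
        if gs is not None:
            out.append(gs)
    return out


def histogram(
    results: Iterable[CaseResult] | pd.DataFrame,
    parameter: str,
    bin_width: float | None = None,
    group_by: str = "role",
) -> HistogramData:
    """Fixed-width, zero-aligned histogram counts per group."""
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    frame = frame[frame["included"]]
    w = bin_width if bin_width is not None else DEFAULT_BIN_WIDTHS.get(parameter, 5.0)
    vals = frame[parameter].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"no determinate values of {parameter} to histogram")
    lo = math.floor(vals.min() / w) * w
    hi = math.ceil(vals.max() / w) * w
    if hi <= lo:
        hi = lo + w
    edges = np.arange(lo, hi + w / 2, w)
    counts: dict[str, np.ndarray] = {}
    for key, grp in frame.groupby(group_by, sort=True):
        gvals = grp[parameter].to_numpy(dtype=float)
        gvals = gvals[~np.isnan(gvals)]
        counts[str(key)], _ = np.histogram(gvals, bins=edges)
    return HistogramData(parameter=parameter, bin_edges=edges, counts=counts)


def flag_outliers(
    results: Iterable[CaseResult] | pd.DataFrame,
    k_sigma: float = 3.0,
    group_by: Sequence[str] = ("class", "role"),
    parameter: str = "phi_attack",
) -> pd.DataFrame:
    """Annotate included cases with outlier flags.

    A case is flagged when its ligand is a D-enantiomer, or when its Φ lies
    more than ``k_sigma`` group standard deviations from the group mean
    (group statistics are computed over the natural-substrate cases only, so
    the outliers cannot drag their own reference).  The ``outlier_rule``
    column records which rule fired.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    frame = frame[frame["included"]].copy()
    d_kinds = {LigandKind.D_ASN.value, LigandKind.D_ASP.value}
    frame["outlier"] = False
    frame["outlier_rule"] = ""
    is_d = frame["ligand_kind"].isin(d_kinds)
    frame.loc[is_d, ["outlier", "outlier_rule"]] = [True, "d-ligand"]
    for _, grp in frame.groupby(list(group_by), sort=False):
        ref = grp[~grp["ligand_kind"].isin(d_kinds)][parameter].dropna()
        if len(ref) < 2:
            continue
        mu, sigma = float(ref.mean()), float(ref.std(ddof=1))
        if sigma == 0:
            continue
        dev = (grp[parameter] - mu).abs() > k_sigma * sigma
        idx = grp.index[dev.fillna(False) & ~grp["ligand_kind"].isin(d_kinds)]
        frame.loc[idx, "outlier"] = True
        frame.loc[idx, "outlier_rule"] = f"|{parameter} - mean| > {k_sigma:g} sigma"
    return frame


def export_report(
    statistics: Sequence[GroupStatistics],
    histograms: Sequence[HistogramData],
    results: Iterable[CaseResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Deterministic CSV + plain-text outputs.

    ``cases.csv``   per-case parameter table (one row per candidate),
    ``groups.csv``  group statistics with μ (σ) formatting,
    ``histograms.csv`` long-format bin counts,
    ``scatter.csv`` (α_BD, α_FL, Φ) triples of included cases for external
    3-D plotting,
    ``report.txt``  human-readable summary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results)
    paths: dict[str, Path] = {}

    cases = frame.copy()
    for col in ("d", "dp", "delta", "alpha_bd", "alpha_fl", "alpha_lw",
                "phi_attack", "tau"):
        cases[col] = pd.to_numeric(cases[col], errors="coerce").round(3)
    paths["cases"] = out_dir / "cases.csv"
    cases.to_csv(paths["cases"], index=False)

    rows = []
    for gs in statistics:
        row: dict[str, object] = {"group": gs.label, "n": gs.n}
        for p in TABLE_PARAMETERS:
            if p in gs.means:
                row[p] = gs.formatted(p)
        row["alpha_fl_indeterminate"] = gs.fl_indeterminate
        row["phi_abs_mean"] = gs.abs_mean_phi
        rows.append(row)
    paths["groups"] = out_dir / "groups.csv"
    pd.DataFrame(rows).to_csv(paths["groups"], index=False)

    hrows = []
    for h in histograms:
        for label, counts in h.counts.items():
            for i, c in enumerate(counts):
                hrows.append(
                    {
                        "parameter": h.parameter,
                        "group": label,
                        "bin_low": round(float(h.bin_edges[i]), 6),
                        "bin_high": round(float(h.bin_edges[i + 1]), 6),
                        "count": int(c),
                    }
                )
    paths["histograms"] = out_dir / "histograms.csv"
    pd.DataFrame(
        hrows, columns=["parameter", "group", "bin_low", "bin_high", "count"]
    ).to_csv(paths["histograms"], index=False)

    scatter = frame[frame["included"]][
        ["structure_id", "chain", "role", "alpha_bd", "alpha_fl", "phi_attack"]
    ].round(3)
    paths["scatter"] = out_dir / "scatter.csv"
    scatter.to_csv(paths["scatter"], index=False)

    n_inc = int(frame["included"].sum())
    n_swap = int(frame.loc[frame["role"] == PRIMARY, "swap_applied"].sum())
    lines = [
        "Nucleophilic-attack geometry survey",
        f"cases analyzed : {len(frame)}",
        f"included       : {n_inc}",
        f"excluded       : {len(frame) - n_inc}",
        f"oxygen swaps   : {n_swap}",
        "",
        f"{'group':<22}{'n':>5}  " + "  ".join(f"{p:>16}" for p in TABLE_PARAMETERS),
    ]
    for gs in statistics:
        lines.append(
            f"{gs.label:<22}{gs.n:>5}  "
            + "  ".join(f"{gs.formatted(p):>16}" for p in TABLE_PARAMETERS if p in gs.means)
        )
    paths["report"] = out_dir / "report.txt"
    paths["report"].write_text("\n".join(lines) + "\n")
    return paths
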