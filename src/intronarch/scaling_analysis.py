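"""Intron-size scaling against genome and gene size.

The central observation being quantified is that the universally
conserved first CDS intron spans three orders of magnitude across
metazoans (tens of bp in sponges and annelids, tens of kb in mammals) and
grows with genome size.  The module fits ordinary least squares on
semi-log (or log-log) transformed coordinates, computes a Spearman rank
correlation with a permutation p-value, and summarises intron size per
clade.

Genome sizes are an external input (TSV: species, genome_size); none are
shipped with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOG_AXES = ("x", "y", "both")
PREDICTORS = ("genome", "gene")


class ScalingError(ValueError):
    pass


@dataclass(frozen=True)
class SizeRecord:
    species_id: str
    ig1_intron_len: float
    gene_span: float
    genome_size: float | None = None
    clade: str | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    predictor: str
    log_axis: str


def read_genome_sizes(tsv_path: str | Path) -> dict[str, float]:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    key = "species" if "species" in df.columns else df.columns[0]
    val = "genome_size" if "genome_size" in df.columns else df.columns[1]
    return dict(zip(df[key].astype(str), df[val].astype(float)))


def _xy(records: Sequence[SizeRecord], predictor: str):
    if predictor not in PREDICTORS:
        raise ScalingError(f"unknown predictor {predictor!r}")
    xs, ys, names = [], [], []
    for r in records:
        x = r.genome_size if predictor == "genome" else r.gene_span
        if x is None:
            continue
        xs.append(float(x))
        ys.append(float(r.ig1_intron_len))
        names.append(r.species_id)
    return np.asarray(xs), np.asarray(ys), names


def fit_semilog(
    records: Sequence[SizeRecord],
    predictor: str = "genome",
    log_axis: str = "x",
) -> RegressionResult:
    """OLS on log10-transformed coordinates.

    ``log_axis`` selects which axis is logarithmic: ``x`` (the default:
    intron size linear against log10 of the predictor), ``y``, or ``both``.
    """
    if log_axis not in LOG_AXES:
        raise ScalingError(f"log_axis must be one of {LOG_AXES}")
    x, y, names = _xy(records, predictor)
    if len(x) < 3:
        raise ScalingError(f"need >= 3 records, got {len(x)}")
    for arr, axis in ((x, "x"), (y, "y")):
        if log_axis in (axis, "both"):
            bad = [n for n, v in zip(names, arr) if v <= 0]
            if bad:
                raise ScalingError(
                    f"non-positive size on log {axis} axis for: {', '.join(bad)}"
                )
    tx = np.log10(x) if log_axis in ("x", "both") else x
    ty = np.log10(y) if log_axis in ("y", "both") else y
    res = stats.linregress(tx, ty)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
        predictor=predictor,
        log_axis=log_axis,
    )


def fit_all_variants(
    records: Sequence[SizeRecord], predictor: str = "genome"
) -> dict[str, RegressionResult]:
    """The three axis-convention variants (log-x, log-y, log-log)."""
    return {axis: fit_semilog(records, predictor, axis) for axis in LOG_AXES}


def rank_correlation(
    records: Sequence[SizeRecord],
    predictor: str = "genome",
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho (midranks for ties) with a permutation p-value.

    The p-value is two-sided: the fraction of label permutations whose
    \\|rho\\| is at least the observed one, with the +1 correction.
    """
    x, y, _ = _xy(records, predictor)
    if len(x) < 3:
        raise ScalingError(f"need >= 3 records, got {len(x)}")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        r = float(np.corrcoef(rx, perm)[0, 1])
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return rho, p


def group_summary(
    records: Sequence[SizeRecord],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-clade median/min/max intron size.

    The result carries a ``gnathostome_exceeds_rest`` attribute flagging
    whether the smallest gnathostome intron exceeds the largest intron of
    every other group (only when a group labelled ``gnathostome`` exists).
    """
    rows = []
    for r in records:
        label = grouping.get(r.species_id) if grouping else r.clade
        if label is None:
            raise ScalingError(f"unknown label for species {r.species_id}")
        rows.append({"clade": label, "ig1_intron_len": r.ig1_intron_len})
    df = pd.DataFrame(rows)
    out = (
        df.groupby("clade")["ig1_intron_len"]
        .agg(["median", "min", "max", "count"])
        .rename(columns={"count": "n"})
        .sort_index()
    )
    if "gnathostome" in out.index:
        rest = out.drop(index="gnathostome")
        out.attrs["gnathostome_exceeds_rest"] = bool(
            rest.empty or out.loc["gnathostome", "min"] > rest["max"].max()
        )
    return out


def scatter_plot(
    records: Sequence[SizeRecord],
    predictor: str,
    log_axis: str,
    path: str | Path,
) -> None:
    """Scatter + fitted line on the chosen axis convention (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = fit_semilog(records, predictor, log_axis)
    x, y, _ = _xy(records, predictor)
    tx = np.log10(x) if log_axis in ("x", "both") else x
    ty = np.log10(y) if log_axis in ("y", "both") else y
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(tx, ty, s=18, color="k")
    grid = np.linspace(tx.min(), tx.max(), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, color="crimson")
    xlab = f"{'log10 ' if log_axis in ('x', 'both') else ''}{predictor} size (bp)"
    ylab = f"{'log10 ' if log_axis in ('y', 'both') else ''}first CDS intron (bp)"
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.set_title(f"R^2 = {fit.r_squared:.2f} (n = {fit.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
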