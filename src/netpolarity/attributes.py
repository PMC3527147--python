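"""Per-gene attribute assembly: evolutionary rates and their correlates.

The attribute table holds, per network gene, the divergence estimates
(omega = dN/dS, dN, dS from a pairwise ortholog comparison), the candidate
confounders of selective constraint (expression level and breadth, codon
bias as ENC, protein-interaction connectivity, number of paralogs),
subcellular compartments, and a positive-selection flag from the M7-vs-M8
likelihood-ratio test.  Values are consumed from upstream tools — nothing
here estimates divergence; this module summarizes, validates and merges.

Missing values are first-class: any field may be absent for any gene and is
kept as NaN (or an empty compartment set), never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "ATTRIBUTE_COLUMNS",
    "COMPARTMENTS",
    "TERM_TO_COMPARTMENT",
    "ExpressionMatrix",
    "summarize_expression",
    "lrt_positive_selection",
    "flag_positive_selection",
    "annotate_compartments",
    "exclusive_compartments",
    "assemble_attribute_table",
    "read_attribute_table",
    "write_attribute_table",
    "validate_attribute_table",
]

log = logging.getLogger(__name__)

ATTRIBUTE_COLUMNS = [
    "omega", "dN", "dS", "expr_level", "expr_breadth", "enc",
    "connectivity", "n_paralogs", "compartments", "possel_p",
]

COMPARTMENTS = ("extracellular", "membrane", "cytoplasm", "nucleus")

#: Default mapping from annotation terms to compartments (cellular-component
#: vocabulary); unknown terms are ignored.
TERM_TO_COMPARTMENT = {
    "extracellular region": "extracellular",
    "plasma membrane": "membrane",
    "cytoplasm": "cytoplasm",
    "nucleus": "nucleus",
}


@dataclass
class ExpressionMatrix:
    """A probe x (tissue, replicate) intensity matrix.

    ``values`` columns are raw array columns; ``replicate_map`` groups them
    into tissues (tissue name -> list of column names).  ``probe_map``
    assigns each probe to at most one gene; unmapped probes are dropped with
    a logged count during summarization.
    """

    values: pd.DataFrame
    probe_map: Mapping[str, str]
    replicate_map: Mapping[str, Sequence[str]]

    def tissue_means(self) -> pd.DataFrame:
        """Average replicate columns into one column per tissue."""
        cols = {}
        for tissue, reps in self.replicate_map.items():
            missing = [c for c in reps if c not in self.values.columns]
            if missing:
                raise KeyError(f"replicate columns absent from matrix: {missing}")
            cols[tissue] = self.values[list(reps)].mean(axis=1)
        return pd.DataFrame(cols)


def summarize_expression(
    matrix: ExpressionMatrix,
    tissues: Sequence[str],
) -> pd.DataFrame:
    """Per-gene expression level and breadth over a selected tissue panel.

    Procedure: replicate columns are averaged per tissue; each probe's level
    is its mean over the selected tissues; for genes matched by several
    probes the probe with the highest level represents the gene; breadth is
    the number of selected tissues in which that probe's value is strictly
    above the global median of the replicate-averaged selected-tissue
    submatrix (all probes, selected tissues).

    Returns a DataFrame indexed by gene with columns ``expr_level`` and
    ``expr_breadth``.
    """
    per_tissue = matrix.tissue_means()
    missing = [t for t in tissues if t not in per_tissue.columns]
    if missing:
        raise KeyError(f"selected tissues absent from matrix: {missing}")
    sub = per_tissue[list(tissues)]

    genes = pd.Series({p: matrix.probe_map.get(p) for p in sub.index})
    unmapped = int(genes.isna().sum())
    if unmapped:
        log.info("summarize_expression: dropped %d unmapped probes", unmapped)
    sub = sub.loc[genes.notna()]
    genes = genes.dropna()

    global_median = float(np.median(sub.to_numpy().ravel()))
    levels = sub.mean(axis=1)

    rows = {}
    for gene, probes in genes.groupby(genes).groups.items():
        best = levels.loc[list(probes)].idxmax()
        breadth = int((sub.loc[best] > global_median).sum())
        rows[gene] = (float(levels.loc[best]), breadth)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["expr_level", "expr_breadth"])
    out.index.name = "gene"
    return out.sort_index()


def lrt_positive_selection(
    lnl_null: float, lnl_alt: float, tolerance: float = 1e-6,
) -> float:
    """P-value of the likelihood-ratio test between nested codon models.

    Twice the log-likelihood difference of the null (all codon omega <= 1)
    and alternative (an extra codon class with omega > 1) models is referred
    to a chi-square distribution with 2 degrees of freedom.  For 2 df this
    upper tail equals exp(-delta), delta the log-likelihood difference.
    A slightly negative delta (numerical noise from the optimizer) is
    clipped to 0; beyond ``tolerance`` a warning is emitted as well.
    """
    delta = lnl_alt - lnl_null
    if delta < -tolerance:
        warnings.warn(
            f"alternative log-likelihood below null by {-delta:.3g}; "
            "statistic clipped to 0", stacklevel=2)
    stat = 2.0 * max(delta, 0.0)
    return float(sps.chi2.sf(stat, df=2))


def flag_positive_selection(
    p_values: Mapping[str, float], q_threshold: float = 0.05,
) -> pd.DataFrame:
    """FDR-correct LRT p-values and flag genes with q below threshold.

    Returns a DataFrame indexed by gene with columns ``q_value`` and
    ``possel_flag``.  Flagged genes form the exclusion set for the
    positive-selection-removed reruns.
    """
    genes = sorted(p_values)
    p = np.array([p_values[g] for g in genes], dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("LRT p-values must lie in [0, 1]")
    q = bh_fdr(p)
    return pd.DataFrame(
        {"q_value": q, "possel_flag": q < q_threshold}, index=pd.Index(genes, name="gene"))


def annotate_compartments(
    annotation: Mapping[str, Sequence[str]],
    term_map: Mapping[str, str] = TERM_TO_COMPARTMENT,
) -> dict[str, frozenset[str]]:
    """Map per-gene annotation term lists to compartment sets.

    Unknown terms are ignored; a gene may belong to several compartments or
    to none.
    """
    return {
        gene: frozenset(term_map[t] for t in terms if t in term_map)
        for gene, terms in annotation.items()
    }


def exclusive_compartments(
    compartments: Mapping[str, frozenset[str]],
) -> dict[str, str]:
    """Genes annotated to exactly one compartment, with that compartment."""
    return {g: next(iter(s)) for g, s in compartments.items() if len(s) == 1}


def _series_from(source: Mapping[str, float] | pd.Series, name: str) -> pd.Series:
    s = pd.Series(source, dtype=float)
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique()
        conflicting = [g for g in dups if s.loc[[g]].nunique() > 1]
        if conflicting:
            raise ValueError(
                f"conflicting duplicate rows in {name!r} for gene(s): "
                f"{sorted(conflicting)}")
        s = s[~s.index.duplicated()]
    s.name = name
    return s


def assemble_attribute_table(
    genes: Sequence[str],
    *,
    omega: Mapping[str, float] | None = None,
    dN: Mapping[str, float] | None = None,
    dS: Mapping[str, float] | None = None,
    expression: pd.DataFrame | None = None,
    enc: Mapping[str, float] | None = None,
    enc_ortholog: Mapping[str, float] | None = None,
    connectivity: Mapping[str, float] | None = None,
    n_paralogs: Mapping[str, float] | None = None,
    compartments: Mapping[str, frozenset[str]] | None = None,
    possel_p: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Merge per-field sources into one row per network gene.

    ``genes`` (normally the network node set) defines the row universe:
    genes absent from a source get a missing value for that field, and
    source entries outside the universe are ignored.  When both ``enc`` and
    ``enc_ortholog`` are given, the gene's ENC is the arithmetic mean of the
    ortholog pair (a single available value is used as-is).  Per-field
    missing counts are logged.
    """
    index = pd.Index(sorted(set(genes)), name="gene")
    table = pd.DataFrame(index=index)
    for name, src in [("omega", omega), ("dN", dN), ("dS", dS)]:
        table[name] = _series_from(src, name).reindex(index) if src is not None else np.nan
    if expression is not None:
        table["expr_level"] = _series_from(
            expression["expr_level"], "expr_level").reindex(index)
        table["expr_breadth"] = _series_from(
            expression["expr_breadth"], "expr_breadth").reindex(index)
    else:
        table["expr_level"] = np.nan
        table["expr_breadth"] = np.nan
    if enc is not None:
        enc_s = _series_from(enc, "enc").reindex(index)
        if enc_ortholog is not None:
            other = _series_from(enc_ortholog, "enc_ortholog").reindex(index)
            enc_s = pd.concat([enc_s, other], axis=1).mean(axis=1)
        table["enc"] = enc_s
    else:
        table["enc"] = np.nan
    table["connectivity"] = (
        _series_from(connectivity, "connectivity").reindex(index)
        if connectivity is not None else np.nan)
    table["n_paralogs"] = (
        _series_from(n_paralogs, "n_paralogs").reindex(index)
        if n_paralogs is not None else np.nan)
    if compartments is not None:
        table["compartments"] = [
            compartments.get(g, frozenset()) for g in index]
    else:
        table["compartments"] = [frozenset() for _ in index]
    table["possel_p"] = (
        _series_from(possel_p, "possel_p").reindex(index)
        if possel_p is not None else np.nan)

    for col in ATTRIBUTE_COLUMNS:
        if col == "compartments":
            continue
        n_missing = int(table[col].isna().sum())
        if n_missing:
            log.info("assemble_attribute_table: %s missing for %d/%d genes",
                     col, n_missing, len(index))
    validate_attribute_table(table)
    return table


def validate_attribute_table(table: pd.DataFrame) -> None:
    """Check value-range invariants; warn on omega/dN/dS inconsistency.

    omega, dN and dS must be non-negative where present.  Where all three
    are present, omega is compared with dN/dS at 5% relative tolerance —
    disagreement warns (model-based omega need not equal the ratio of
    averaged rates exactly) but is never corrected.
    """
    for col in ("omega", "dN", "dS"):
        vals = table[col].dropna()
        if (vals < 0).any():
            raise ValueError(f"{col} must be non-negative")
    breadth = table["expr_breadth"].dropna()
    if ((breadth < 0) | (breadth != breadth.round())).any():
        raise ValueError("expr_breadth must be a non-negative integer count")
    p = table["possel_p"].dropna()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("possel_p must lie in [0, 1]")
    full = table.dropna(subset=["omega", "dN", "dS"])
    full = full[full["dS"] > 0]
    if len(full):
        ratio = full["dN"] / full["dS"]
        rel = np.abs(ratio - full["omega"]) / np.maximum(full["omega"], 1e-12)
        bad = rel > 0.05
        if bad.any():
            warnings.warn(
                f"omega differs from dN/dS by >5% for {int(bad.sum())} gene(s)",
                stacklevel=2)


def write_attribute_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize as TSV; compartment sets become comma-joined tokens."""
    out = table.copy()
    out["compartments"] = [
        ",".join(sorted(s)) if s else "" for s in out["compartments"]]
    out.to_csv(path, sep="\t")


def read_attribute_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV dialect written by :func:`write_attribute_table`."""
    table = pd.read_csv(path, sep="\t", index_col="gene")
    comp = table.get("compartments")
    if comp is None:
        table["compartments"] = [frozenset() for _ in table.index]
    else:
        table["compartments"] = [
            frozenset(str(s).split(",")) if isinstance(s, str) and s else frozenset()
            for s in comp]
    for col in ATTRIBUTE_COLUMNS:
        if col != "compartments" and col not in table.columns:
            table[col] = np.nan
    validate_attribute_table(table)
    return table
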