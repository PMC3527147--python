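"""The polarity analyses: paired, extreme-group, correlation, and controls.

Three complementary views of the same question — does a gene's
upstream/downstream position in the directed signaling network predict the
strength of purifying selection acting on it?

1. *Paired target comparison*: each gene with direct downstream targets is
   compared against the central value of its targets' values, and the
   greater/less counts feed an exact sign test.  The central value is the
   median for an odd number of targets; for an even number one of the two
   middle order statistics is chosen at random (averaging them would be
   sensitive to the asymmetry of the omega distribution).
2. *Extreme-group comparison*: Mann-Whitney U between genes at the extreme
   upstream (out-degree > 0, in-degree = 0) and extreme downstream
   (in-degree > 0, out-degree = 0) positions.
3. *Hierarchy correlations*: Spearman rank correlation of the value against
   in-degree, out-degree and the downstream-reachability count H.

Each view has a confound-controlled variant: the paired and extreme-group
tests rerun on OLS residuals of the value against a factor, and the
correlation analyses become rank-based partial correlations (binary
upstream/downstream code, or H, against the value given one or more
controls).  Stratified (per-compartment) and gene-set-exclusion reruns
complete the picture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .network import (
    SignalingNetwork,
    classify_positions,
    degree_profile,
    hierarchy_profiles,
    pathway_positions,
)
from .attributes import COMPARTMENTS, exclusive_compartments
from .stats import ContingencyTable2x2, TestResult

__all__ = [
    "PairedComparisonResult",
    "ReportEntry",
    "AnalysisReport",
    "central_target_value",
    "paired_target_analysis",
    "extreme_group_analysis",
    "hierarchy_correlation_analysis",
    "confound_controlled_analysis",
    "stratified_compartment_analysis",
    "exclusion_rerun",
    "ras_pathway_analysis",
    "run_full_analysis",
]

log = logging.getLogger(__name__)

RATE_VARIABLES = ("omega", "dN", "dS")
FACTOR_VARIABLES = ("expr_level", "expr_breadth", "enc", "connectivity",
                    "n_paralogs")
TABLE1_VARIABLES = RATE_VARIABLES + FACTOR_VARIABLES


@dataclass
class PairedComparisonResult:
    """Tallies and p-value of one paired focal-vs-targets comparison.

    ``p_value`` is None when every informative gene tied (no non-tie pairs
    to test).  ``seed_sensitive`` counts genes whose central value involved
    a random draw (even number of non-missing targets) — the maximum amount
    by which a different seed could shift the tallies.
    """

    variable: str
    n_informative: int
    n_greater: int
    n_less: int
    n_tie: int
    p_value: float | None
    seed_sensitive: int = 0

    @property
    def test(self) -> TestResult | None:
        if self.n_greater + self.n_less == 0:
            return None
        return st.exact_sign_test(self.n_greater, self.n_less)


@dataclass
class ReportEntry:
    """One labeled result: which analysis, on which gene subset, with which
    control, produced it."""

    analysis: str
    variable: str
    subset: str = "all"
    control: str = "none"
    result: TestResult | PairedComparisonResult | None = None
    note: str = ""

    def row(self) -> dict:
        out = {
            "analysis": self.analysis, "subset": self.subset,
            "variable": self.variable, "control": self.control,
            "n": "", "n_greater": "", "n_less": "", "n_tie": "",
            "statistic": "", "p": "", "note": self.note,
        }
        r = self.result
        if isinstance(r, PairedComparisonResult):
            out.update(n=r.n_informative, n_greater=r.n_greater,
                       n_less=r.n_less, n_tie=r.n_tie,
                       p="" if r.p_value is None else repr(r.p_value))
        elif isinstance(r, TestResult):
            out.update(n=r.n, statistic=repr(r.statistic), p=repr(r.p_value))
        return out


@dataclass
class AnalysisReport:
    """An ordered collection of labeled results."""

    entries: list[ReportEntry] = field(default_factory=list)

    def add(self, entry: ReportEntry) -> None:
        self.entries.append(entry)

    def extend(self, other: "AnalysisReport") -> None:
        self.entries.extend(other.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.row() for e in self.entries])

    def get(self, analysis: str, variable: str, subset: str = "all",
            control: str = "none") -> ReportEntry:
        for e in self.entries:
            if (e.analysis, e.variable, e.subset, e.control) == (
                    analysis, variable, subset, control):
                return e
        raise KeyError((analysis, variable, subset, control))


def central_target_value(
    values: Sequence[float], rng: np.random.Generator,
) -> float:
    """Central value of a target list: the median order statistic.

    Odd count: the middle value.  Even count: one of the two middle order
    statistics, chosen uniformly at random — never their average.
    Missing values must be removed by the caller.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("central_target_value requires at least one value")
    if arr.size % 2 == 1:
        return float(arr[arr.size // 2])
    mid = arr.size // 2
    return float(arr[mid - 1 + rng.integers(0, 2)])


def paired_target_analysis(
    network: SignalingNetwork,
    values: Mapping[str, float],
    rng: np.random.Generator,
    variable: str = "value",
    tie_tolerance: float = 0.0,
    restrict_to: set[str] | None = None,
) -> PairedComparisonResult:
    """Compare each gene's value with the central value of its targets.

    A gene is informative if it has out-degree > 0, a non-missing value,
    and at least one target with a non-missing value.  ``restrict_to``
    limits both focal genes and targets to a subset (used by the
    compartment-stratified analyses).  Genes are visited in sorted order
    and random draws come from one stream, so results do not depend on
    input ordering.  Ties (|difference| <= ``tie_tolerance``) are excluded
    from the sign test.
    """
    g = network.graph

    def val(x: str) -> float:
        v = values.get(x, np.nan)
        return float(v) if v is not None else np.nan

    n_inf = n_gt = n_lt = n_tie = n_even = 0
    for gene in sorted(network.nodes):
        if restrict_to is not None and gene not in restrict_to:
            continue
        if g.out_degree(gene) == 0:
            continue
        v = val(gene)
        if np.isnan(v):
            continue
        targets = [t for t in g.successors(gene)
                   if restrict_to is None or t in restrict_to]
        tvals = [val(t) for t in targets]
        tvals = [x for x in tvals if not np.isnan(x)]
        if not tvals:
            continue
        n_inf += 1
        if len(tvals) % 2 == 0:
            n_even += 1
        central = central_target_value(tvals, rng)
        diff = v - central
        if abs(diff) <= tie_tolerance:
            n_tie += 1
        elif diff > 0:
            n_gt += 1
        else:
            n_lt += 1
    if n_inf == 0:
        raise ValueError("paired_target_analysis: no informative genes")
    p = None
    if n_gt + n_lt > 0:
        p = st.exact_sign_test(n_gt, n_lt).p_value
    return PairedComparisonResult(variable, n_inf, n_gt, n_lt, n_tie, p,
                                  seed_sensitive=n_even)


def _class_values(
    network: SignalingNetwork, values: Mapping[str, float],
) -> tuple[list[float], list[float]]:
    classes = classify_positions(degree_profile(network))
    up, down = [], []
    for gene, cls in classes.items():
        v = values.get(gene, np.nan)
        if v is None or np.isnan(v):
            continue
        if cls == "upstream":
            up.append(float(v))
        elif cls == "downstream":
            down.append(float(v))
    return up, down


def extreme_group_analysis(
    network: SignalingNetwork,
    values: Mapping[str, float],
    variable: str = "value",
) -> TestResult:
    """Mann-Whitney U between extreme-upstream and extreme-downstream genes."""
    up, down = _class_values(network, values)
    if not up or not down:
        raise ValueError(
            "extreme_group_analysis requires values in both extreme classes")
    res = st.mann_whitney(up, down)
    res.extras["variable"] = variable
    return res


def hierarchy_correlation_analysis(
    network: SignalingNetwork,
    values: Mapping[str, float],
    variable: str = "value",
    profiles: pd.DataFrame | None = None,
) -> dict[str, TestResult | None]:
    """Spearman correlation of the value with in-degree, out-degree and H.

    A constant hierarchy metric yields None for that metric rather than an
    error (the other correlations remain informative).
    """
    if profiles is None:
        profiles = hierarchy_profiles(network)
    genes = list(profiles.index)
    v = np.array([float(values.get(g, np.nan))
                  if values.get(g, np.nan) is not None else np.nan
                  for g in genes])
    if np.sum(~np.isnan(v)) < 10:
        raise ValueError("hierarchy_correlation_analysis requires >= 10 values")
    out: dict[str, TestResult | None] = {}
    for metric in ("in_degree", "out_degree", "H"):
        x = profiles[metric].to_numpy(dtype=float)
        try:
            out[metric] = st.spearman(x, v)
        except ValueError:
            log.warning("constant metric %s for variable %s", metric, variable)
            out[metric] = None
    return out


def confound_controlled_analysis(
    network: SignalingNetwork,
    values: Mapping[str, float],
    factor: Mapping[str, float],
    mode: str,
    rng: np.random.Generator | None = None,
    extra_controls: Sequence[Mapping[str, float]] = (),
    variable: str = "value",
    control: str = "factor",
    profiles: pd.DataFrame | None = None,
) -> TestResult | PairedComparisonResult:
    """Rerun a polarity analysis after discounting a confounding factor.

    Modes
    -----
    ``residual-paired`` / ``residual-extreme``
        OLS-residualize the value on the factor (complete cases), then rerun
        the paired sign test / the extreme-group Mann-Whitney on residuals.
    ``partial-binary``
        Rank-based partial correlation of the binary upstream/downstream
        code with the value, given the factor (and ``extra_controls``).
    ``partial-H``
        Same, with the downstream-reachability count H in place of the
        binary code.
    """
    genes = sorted(network.nodes)

    def col(mapping: Mapping[str, float]) -> np.ndarray:
        return np.array([
            float(mapping.get(g, np.nan))
            if mapping.get(g, np.nan) is not None else np.nan
            for g in genes])

    v = col(values)
    f = col(factor)
    if mode in ("residual-paired", "residual-extreme"):
        resid = st.residualize(v, f)
        resid_map = {g: resid[i] for i, g in enumerate(genes)
                     if not np.isnan(resid[i])}
        if mode == "residual-paired":
            if rng is None:
                raise ValueError("residual-paired mode requires an rng")
            return paired_target_analysis(network, resid_map, rng,
                                          variable=variable)
        return extreme_group_analysis(network, resid_map, variable=variable)
    if mode in ("partial-binary", "partial-H"):
        controls = [f] + [col(c) for c in extra_controls]
        names = [control] + [f"extra_{i}" for i in range(len(extra_controls))]
        if mode == "partial-binary":
            classes = classify_positions(degree_profile(network))
            x = col(st.binary_encode(classes))
        else:
            if profiles is None:
                profiles = hierarchy_profiles(network)
            x = profiles.loc[genes, "H"].to_numpy(dtype=float)
        res = st.partial_spearman(x, v, controls, control_names=names)
        res.extras["mode"] = mode
        res.extras["variable"] = variable
        return res
    raise ValueError(f"unknown mode: {mode!r}")


def stratified_compartment_analysis(
    network: SignalingNetwork,
    values: Mapping[str, float],
    compartments: Mapping[str, frozenset[str]],
    rng: np.random.Generator,
    variable: str = "value",
) -> AnalysisReport:
    """Per-compartment polarity analyses plus compartment-distribution tests.

    For each compartment: (a) the paired comparison restricted to
    focal-target pairs both carrying the compartment; (b) the extreme-group
    Mann-Whitney among the compartment's genes; (c) Fisher's exact test of
    compartment membership against the upstream/downstream split.  Finally
    a Kruskal-Wallis test compares values across genes belonging to exactly
    one compartment.  A compartment with too few informative genes yields
    an entry marked insufficient rather than an error.
    """
    report = AnalysisReport()
    classes = classify_positions(degree_profile(network))
    for comp in COMPARTMENTS:
        members = {g for g, s in compartments.items() if comp in s}
        # (a) paired comparison within the compartment
        entry = ReportEntry("paired", variable, subset=f"compartment:{comp}")
        try:
            entry.result = paired_target_analysis(
                network, values, rng, variable=variable, restrict_to=members)
            if entry.result.n_greater + entry.result.n_less < 2:
                entry.note = "insufficient"
        except ValueError:
            entry.note = "insufficient"
        report.add(entry)
        # (b) extreme-group comparison within the compartment
        entry = ReportEntry("extreme", variable, subset=f"compartment:{comp}")
        sub_values = {g: values[g] for g in members if g in values}
        try:
            entry.result = extreme_group_analysis(network, sub_values,
                                                  variable=variable)
        except ValueError:
            entry.note = "insufficient"
        report.add(entry)
        # (c) compartment membership across upstream/downstream classes
        up = [g for g, c in classes.items() if c == "upstream"]
        down = [g for g, c in classes.items() if c == "downstream"]
        a = sum(1 for g in up if g in members)
        c = sum(1 for g in down if g in members)
        entry = ReportEntry("fisher-membership", comp,
                            subset="upstream-vs-downstream")
        try:
            entry.result = st.fisher_2x2(ContingencyTable2x2(
                a, len(up) - a, c, len(down) - c))
        except ValueError:
            entry.note = "insufficient"
        report.add(entry)

    exclusive = exclusive_compartments(compartments)
    groups = []
    for comp in COMPARTMENTS:
        vals = [float(values[g]) for g, c in exclusive.items()
                if c == comp and g in values
                and values[g] is not None and not np.isnan(values[g])]
        if vals:
            groups.append(vals)
    entry = ReportEntry("kruskal-exclusive-compartments", variable)
    if len(groups) >= 2:
        entry.result = st.kruskal_wallis(groups)
    else:
        entry.note = "insufficient"
    report.add(entry)
    return report


def exclusion_rerun(
    network: SignalingNetwork,
    values: Mapping[str, float],
    exclude: Iterable[str],
    label: str,
    rng: np.random.Generator,
    variable: str = "value",
    profiles: pd.DataFrame | None = None,
) -> AnalysisReport:
    """Rerun the three core analyses with a gene set's values removed.

    Excluded genes keep their place in the graph (degrees and H are
    unchanged) but contribute no value — neither as focal genes nor as
    targets, nor to any group or correlation.
    """
    exclude = set(exclude)
    kept = {g: v for g, v in values.items() if g not in exclude}
    report = AnalysisReport()
    subset = f"exclude:{label}"

    entry = ReportEntry("paired", variable, subset=subset)
    try:
        entry.result = paired_target_analysis(network, kept, rng,
                                              variable=variable)
    except ValueError:
        entry.note = "insufficient"
    report.add(entry)

    entry = ReportEntry("extreme", variable, subset=subset)
    try:
        entry.result = extreme_group_analysis(network, kept, variable=variable)
    except ValueError:
        entry.note = "insufficient"
    report.add(entry)

    try:
        corr = hierarchy_correlation_analysis(network, kept, variable=variable,
                                              profiles=profiles)
        for metric, res in corr.items():
            report.add(ReportEntry("correlation", f"{variable}~{metric}",
                                   subset=subset, result=res,
                                   note="" if res else "constant metric"))
    except ValueError:
        for metric in ("in_degree", "out_degree", "H"):
            report.add(ReportEntry("correlation", f"{variable}~{metric}",
                                   subset=subset, note="insufficient"))
    return report


def ras_pathway_analysis(
    pathway: SignalingNetwork,
    source: str,
    upstream_set: Iterable[str],
    values: Mapping[str, float],
    factors: Mapping[str, Mapping[str, float]] | None = None,
) -> AnalysisReport:
    """Case-study analysis of a single pathway with a designated source.

    Pathway position is the shortest directed step count from the source
    (source = 0); genes unreachable from the source are dropped with a
    logged count.  The value (and each factor) is Spearman-correlated with
    position, and a Mann-Whitney compares the declared upstream gene set
    against the remaining (downstream) pathway genes.
    """
    positions = pathway_positions(pathway, source)
    unreachable = sorted(set(pathway.nodes) - set(positions))
    if unreachable:
        log.info("ras_pathway_analysis: %d genes unreachable from %s: %s",
                 len(unreachable), source, unreachable)
    report = AnalysisReport()

    genes = sorted(positions)
    pos = np.array([positions[g] for g in genes], dtype=float)

    def col(mapping: Mapping[str, float]) -> np.ndarray:
        return np.array([
            float(mapping.get(g, np.nan))
            if mapping.get(g, np.nan) is not None else np.nan
            for g in genes])

    v = col(values)
    entry = ReportEntry("pathway-correlation", "value~position")
    try:
        entry.result = st.spearman(pos, v)
    except ValueError:
        entry.note = "insufficient"
    report.add(entry)
    for name, factor in (factors or {}).items():
        f = col(factor)
        for label, (x, y) in {
            f"{name}~position": (pos, f),
            f"value~{name}": (f, v),
        }.items():
            entry = ReportEntry("pathway-correlation", label)
            try:
                entry.result = st.spearman(x, y)
            except ValueError:
                entry.note = "insufficient"
            report.add(entry)

    upstream_set = set(upstream_set)
    up = [float(values[g]) for g in genes
          if g in upstream_set and g in values and not np.isnan(float(values[g]))]
    down = [float(values[g]) for g in genes
            if g not in upstream_set and g in values
            and not np.isnan(float(values[g]))]
    entry = ReportEntry("pathway-extreme", "value",
                        subset="declared-upstream-vs-rest")
    if up and down:
        entry.result = st.mann_whitney(up, down)
    else:
        entry.note = "insufficient"
    report.add(entry)
    return report


def _values_of(attributes: pd.DataFrame, column: str) -> dict[str, float]:
    return {g: float(v) for g, v in attributes[column].items()
            if not pd.isna(v)}


def run_full_analysis(config) -> AnalysisReport:
    """Execute the complete analysis suite described by a run configuration.

    Covers: hierarchy computation; the paired, extreme-group and
    correlation analyses for every attribute; correlate-vs-rate
    correlations; residual- and partial-correlation confound controls for
    the rate variables; compartment stratification; positive-selection and
    configured gene-set exclusions; and the pathway case study when
    configured.  Deterministic given the config seed.  See
    :mod:`netpolarity.config` for the configuration surface.
    """
    from .config import load_inputs  # deferred: config imports this module

    network, attributes, run = load_inputs(config)
    rng = np.random.default_rng(run.seed)
    profiles = hierarchy_profiles(network)
    report = AnalysisReport()

    # Paired, extreme-group and hierarchy-correlation analyses per variable
    for var in TABLE1_VARIABLES:
        vals = _values_of(attributes, var)
        entry = ReportEntry("paired", var)
        try:
            entry.result = paired_target_analysis(
                network, vals, rng, variable=var,
                tie_tolerance=run.tie_tolerance)
        except ValueError:
            entry.note = "insufficient"
        report.add(entry)
    for var in TABLE1_VARIABLES:
        vals = _values_of(attributes, var)
        entry = ReportEntry("extreme", var)
        try:
            entry.result = extreme_group_analysis(network, vals, variable=var)
        except ValueError:
            entry.note = "insufficient"
        report.add(entry)
    for var in TABLE1_VARIABLES:
        vals = _values_of(attributes, var)
        try:
            corr = hierarchy_correlation_analysis(
                network, vals, variable=var, profiles=profiles)
        except ValueError:
            corr = {m: None for m in ("in_degree", "out_degree", "H")}
        for metric, res in corr.items():
            report.add(ReportEntry(
                "correlation", f"{var}~{metric}", result=res,
                note="" if res else "unavailable"))

    # Correlates of the rate variables (factor-vs-rate correlations)
    for rate in ("omega", "dN"):
        rv = attributes[rate]
        for factor in FACTOR_VARIABLES:
            entry = ReportEntry("correlate", f"{rate}~{factor}")
            try:
                entry.result = st.spearman(attributes[factor], rv)
            except ValueError:
                entry.note = "insufficient"
            report.add(entry)

    # Confound control: residual and partial-correlation variants
    for rate in ("omega", "dN"):
        vals = _values_of(attributes, rate)
        for factor in FACTOR_VARIABLES:
            fvals = _values_of(attributes, factor)
            for mode, analysis in [
                ("residual-paired", "paired"),
                ("residual-extreme", "extreme"),
                ("partial-binary", "partial-binary"),
                ("partial-H", "partial-H"),
            ]:
                entry = ReportEntry(analysis, rate, control=factor)
                try:
                    entry.result = confound_controlled_analysis(
                        network, vals, fvals, mode, rng=rng,
                        variable=rate, control=factor, profiles=profiles)
                except ValueError as exc:
                    entry.note = f"unavailable: {exc}"
                report.add(entry)

    # Compartment stratification (rate variables)
    comp = dict(attributes["compartments"].items())
    for rate in ("omega", "dN"):
        vals = _values_of(attributes, rate)
        sub = stratified_compartment_analysis(network, vals, comp, rng,
                                              variable=rate)
        report.extend(sub)

    # Exclusion reruns: positive selection, then configured sets
    exclusions: dict[str, set[str]] = {}
    possel = attributes["possel_p"].dropna()
    if len(possel):
        from .attributes import flag_positive_selection
        flags = flag_positive_selection(dict(possel.items()),
                                        q_threshold=run.q_threshold)
        exclusions["positive-selection"] = set(
            flags.index[flags["possel_flag"]])
    for label, genes in run.exclusion_sets.items():
        exclusions[label] = set(genes)
    for label, excl in exclusions.items():
        for rate in ("omega", "dN"):
            vals = _values_of(attributes, rate)
            sub = exclusion_rerun(network, vals, excl, label, rng,
                                  variable=rate, profiles=profiles)
            report.extend(sub)

    # Pathway case study
    if run.ras is not None:
        vals = _values_of(attributes, "omega")
        factors = {f: _values_of(attributes, f)
                   for f in ("expr_level", "expr_breadth", "connectivity")}
        sub = ras_pathway_analysis(network, run.ras.source,
                                   run.ras.upstream, vals, factors)
        report.extend(sub)
    return report
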