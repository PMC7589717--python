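"""Nested variance components, P_ST, heritability analogue, R_ST and the
phenotype-vs-marker differentiation contrast.

The quantitative-trait side decomposes each trait under the fully nested
random-effects model

    Y = mu + region + population(region) + haplotype(population) + plant

fitted by REML (default) or, for balanced designs, by nested-ANOVA method
of moments.  With one measurement per plant (replicates are averaged
beforehand) the plant effect is the model residual, so the fitted residual
variance is reported as ``v_plant`` and ``v_residual`` is 0 and flagged
as confounded.

P_ST = V_AP / (V_AP + 2 V_WP) with V_AP the among-population and V_WP the
among-plant (within-population) component; the heritability analogue is
h^2 = v_plant / total variance.  R_ST partitions allele-size variance (in
repeat units, presence-weighted) within vs. among groups under the
stepwise-mutation rationale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from polydiff.data_model import (
    FACTOR_COLUMNS,
    DistanceMatrix,
    MicrosatDataset,
    records_to_frame,
)

_FACTORS = ["region", "population", "haplotype", "plant"]


def _as_frame(phenotypes) -> pd.DataFrame:
    if hasattr(phenotypes, "columns"):
        return phenotypes.copy()
    return records_to_frame(list(phenotypes))


# ---------------------------------------------------------------------------
# variance components


@dataclass
class VarianceComponents:
    """Estimated variances of the nested random effects for one trait.

    ``flags`` records estimation caveats per component (negative estimates
    truncated at 0, single-level factors, confounded factors).
    """

    trait: str
    v_region: float
    v_population: float
    v_haplotype: float
    v_plant: float
    v_residual: float
    flags: dict = field(default_factory=dict)
    method: str = "reml"

    @property
    def v_ap(self) -> float:
        """Among-population variance (the P_ST numerator)."""
        return self.v_population

    @property
    def v_wp(self) -> float:
        """Within-population, among-plant variance (the P_ST denominator term)."""
        return self.v_plant

    @property
    def total(self) -> float:
        return (
            self.v_region
            + self.v_population
            + self.v_haplotype
            + self.v_plant
            + self.v_residual
        )

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "region": self.v_region,
                "population": self.v_population,
                "haplotype": self.v_haplotype,
                "plant": self.v_plant,
                "residual": self.v_residual,
            },
            name=self.trait,
        )


def pst(v_ap: float, v_wp: float) -> float:
    """Phenotypic differentiation P_ST = V_AP / (V_AP + 2 V_WP)."""
    if v_ap < 0 or v_wp < 0:
        raise ValueError("variance components must be >= 0")
    denom = v_ap + 2.0 * v_wp
    if denom == 0:
        raise ValueError("P_ST undefined when both components are 0")
    return v_ap / denom


def heritability(components) -> float:
    """Heritability analogue: among-plant variance over total variance.

    Accepts a :class:`VarianceComponents` or the sequence
    ``(v_region, v_population, v_haplotype, v_plant, v_residual)``.
    """
    if isinstance(components, VarianceComponents):
        v_plant, total = components.v_plant, components.total
    else:
        v_region, v_population, v_haplotype, v_plant, v_residual = components
        total = v_region + v_population + v_haplotype + v_plant + v_residual
    if total <= 0:
        raise ValueError("total variance must be > 0")
    return v_plant / total


def _collapse_replicates(frame: pd.DataFrame, trait: str):
    """One row per plant (replicates averaged) plus the replicate-level
    residual information.

    Returns ``(plant_data, v_residual, r_mean)`` where ``v_residual`` is the
    pooled within-plant variance (None without replication) and ``r_mean``
    the mean number of measurements per plant.
    """
    cols = _FACTORS + [trait]
    data = frame[cols].dropna(subset=[trait])
    groups = data.groupby(_FACTORS, sort=False)[trait]
    counts = groups.size()
    plant_data = groups.mean().reset_index()
    if (counts > 1).any():
        dev = data[trait] - groups.transform("mean")
        df = int((counts - 1).sum())
        v_residual = float((dev**2).sum() / df) if df > 0 else 0.0
        return plant_data, v_residual, float(counts.mean())
    return plant_data, None, 1.0


def _screen_factors(data: pd.DataFrame) -> tuple[list[str], dict]:
    """Identify estimable nested factors and flag the dropped ones."""
    flags: dict = {}
    usable: list[str] = []
    if data["region"].nunique() >= 2:
        usable.append("region")
    else:
        flags["region"] = "single_level"
    if data["population"].nunique() >= 2:
        usable.append("population")
    else:
        flags["population"] = "single_level"
    haplos_per_pop = data.groupby("population")["haplotype"].nunique()
    if (haplos_per_pop > 1).any():
        usable.append("haplotype")
    elif data["haplotype"].nunique() >= 2:
        flags["haplotype"] = "confounded_with_population"
    else:
        flags["haplotype"] = "single_level"
    return usable, flags


def _nested_keys(data: pd.DataFrame) -> pd.DataFrame:
    """Concatenated labels enforcing the nesting hierarchy."""
    out = data.copy()
    out["_region"] = out["region"].astype(str)
    out["_population"] = out["_region"] + "/" + out["population"].astype(str)
    out["_haplotype"] = out["_population"] + "/" + out["haplotype"].astype(str)
    return out


def _reml_components(data: pd.DataFrame, trait: str) -> tuple[dict, dict]:
    import statsmodels.regression.mixed_linear_model as mlm

    usable, flags = _screen_factors(data)
    est = {"region": 0.0, "population": 0.0, "haplotype": 0.0}
    if not usable:
        resid = float(data[trait].var(ddof=1))
        return {**est, "plant": resid}, flags
    keyed = _nested_keys(data)
    vc_formula = {f: f"0 + C(_{f})" for f in usable}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mlm.MixedLM.from_formula(
            f"{trait} ~ 1",
            data=keyed,
            groups=np.ones(len(keyed)),
            vc_formula=vc_formula,
        )
        result = model.fit(reml=True)
    fitted = dict(zip(model.exog_vc.names, np.asarray(result.vcomp, dtype=float)))
    for f in usable:
        value = fitted[f]
        if value < 0:
            flags[f] = "truncated"
            value = 0.0
        est[f] = float(value)
    est["plant"] = float(result.scale)
    return est, flags


def _anova_components(data: pd.DataFrame, trait: str) -> tuple[dict, dict]:
    """Henderson I / nested-ANOVA estimates; balanced designs only."""
    usable, flags = _screen_factors(data)
    keyed = _nested_keys(data)
    level_cols = [f"_{f}" for f in ("region", "population", "haplotype") if f in usable]
    y = keyed[trait].to_numpy(dtype=float)
    n = len(y)

    # verify balance at every nesting level
    sizes_per_level = []
    for col in level_cols:
        sizes = keyed.groupby(col, sort=False)[trait].size()
        if sizes.nunique() != 1:
            raise ValueError("method-of-moments estimator requires a balanced design")
        sizes_per_level.append(int(sizes.iloc[0]))
    counts = [len(keyed.groupby(col, sort=False)) for col in level_cols]
    for parent_col, child_col in zip(level_cols, level_cols[1:]):
        children = keyed.groupby(parent_col, sort=False)[child_col].nunique()
        if children.nunique() != 1:
            raise ValueError("method-of-moments estimator requires a balanced design")

    grand = y.mean()
    ms, dfs = [], []
    prev_means = pd.Series(grand, index=keyed.index)
    prev_groups = 1
    for col, size, count in zip(level_cols, sizes_per_level, counts):
        means = keyed.groupby(col, sort=False)[trait].transform("mean")
        ss = float(((means - prev_means) ** 2).sum())
        df = count - prev_groups
        ms.append(ss / df)
        dfs.append(df)
        prev_means = means
        prev_groups = count
    ss_within = float(((y - prev_means) ** 2).sum())
    df_within = n - prev_groups
    if df_within <= 0:
        raise ValueError("no within-group replication at the lowest level")
    ms_within = ss_within / df_within

    est = {"region": 0.0, "population": 0.0, "haplotype": 0.0, "plant": ms_within}
    ms_below = ms + [ms_within]
    for idx in range(len(level_cols) - 1, -1, -1):
        factor = level_cols[idx][1:]
        comp = (ms[idx] - ms_below[idx + 1]) / sizes_per_level[idx]
        if comp < 0:
            flags[factor] = "truncated"
            comp = 0.0
        est[factor] = float(comp)
    return est, flags


def estimate_variance_components(
    phenotypes, trait: str, method: str = "reml"
) -> VarianceComponents:
    """Fit the nested random-effects decomposition for one trait.

    method="reml" uses a mixed linear model with variance components for
    region, population(region) and haplotype(population); method="anova"
    uses nested-ANOVA moments (balanced designs only).  Replicate
    measurements per plant, when present, separate the residual (pooled
    within-plant variance) from the plant effect; with one measurement per
    plant the two are confounded, the plant-level residual is reported as
    ``v_plant`` and ``v_residual`` is 0 and flagged.
    """
    frame = _as_frame(phenotypes)
    if trait not in frame.columns:
        raise KeyError(trait)
    data, v_residual, r_mean = _collapse_replicates(frame, trait)
    if data["population"].nunique() < 2:
        warnings.warn("single population: among-population component fixed at 0")
    if len(data) < 3:
        raise ValueError("need >= 3 plant-level observations")
    if method == "reml":
        est, flags = _reml_components(data, trait)
    elif method == "anova":
        est, flags = _anova_components(data, trait)
    else:
        raise ValueError(f"unknown method {method!r}")
    if v_residual is None:
        v_plant = est["plant"]
        v_resid_out = 0.0
        flags["residual"] = "confounded_with_plant"
    else:
        # plant-mean residual has variance v_plant + v_residual / r
        v_plant = est["plant"] - v_residual / r_mean
        if v_plant < 0:
            flags["plant"] = "truncated"
            v_plant = 0.0
        v_resid_out = v_residual
    return VarianceComponents(
        trait=trait,
        v_region=est["region"],
        v_population=est["population"],
        v_haplotype=est["haplotype"],
        v_plant=v_plant,
        v_residual=v_resid_out,
        flags=flags,
        method=method,
    )


# ---------------------------------------------------------------------------
# statsmodels-style model / results objects


class NestedTraitModel:
    """Nested random-effects model for a single quantitative trait.

    Parameters
    ----------
    data : DataFrame with region/population/haplotype/plant factors plus
        trait columns (replicate rows per plant are averaged at fit time).
    trait : trait column to decompose.
    """

    def __init__(self, data, trait: str):
        self.data = _as_frame(data)
        if trait not in self.data.columns:
            raise KeyError(trait)
        self.trait = trait

    @classmethod
    def from_records(cls, records, trait: str) -> "NestedTraitModel":
        return cls(records_to_frame(list(records)), trait)

    def fit(self, method: str = "reml") -> "NestedTraitResults":
        components = estimate_variance_components(self.data, self.trait, method=method)
        return NestedTraitResults(self, components)


class NestedTraitResults:
    """Variance components with the derived differentiation statistics."""

    def __init__(self, model: NestedTraitModel, components: VarianceComponents):
        self.model = model
        self.components = components

    @property
    def pst(self) -> float:
        return pst(self.components.v_ap, self.components.v_wp)

    @property
    def heritability(self) -> float:
        return heritability(self.components)

    def summary(self) -> pd.DataFrame:
        comp = self.components
        rows = comp.as_series().to_frame("variance")
        rows["flag"] = [comp.flags.get(k, "") for k in rows.index]
        derived = pd.DataFrame(
            {"variance": [self.pst, self.heritability], "flag": ["", ""]},
            index=["P_ST", "h2"],
        )
        return pd.concat([rows, derived])

    def __repr__(self) -> str:
        return (
            f"<NestedTraitResults trait={self.components.trait!r} "
            f"P_ST={self.pst:.3f} h2={self.heritability:.3f}>"
        )


# ---------------------------------------------------------------------------
# R_ST


@dataclass
class RstResult:
    """Allele-size variance partition: overall, per-locus and pairwise."""

    overall: float
    per_locus: pd.Series
    pairwise: DistanceMatrix
    jackknife_se: float
    grouping: dict

    def __repr__(self) -> str:
        return f"<RstResult overall={self.overall:.3f} se={self.jackknife_se:.3f}>"


def _locus_observations(dataset: MicrosatDataset, group_of: dict):
    """Per locus: allele sizes in repeat units with their group labels."""
    out = {}
    for loc in dataset.loci:
        values, groups = [], []
        for ind in dataset.individuals:
            grp = group_of[dataset.population_of[ind]]
            for allele in dataset.genotypes[ind][loc.name].sizes:
                values.append(allele / loc.repeat_unit)
                groups.append(grp)
        out[loc.name] = (np.asarray(values, dtype=float), np.asarray(groups))
    return out


def _rst_from_obs(obs: dict, groups_subset=None) -> tuple[float, pd.Series]:
    s_tot_sum = s_w_sum = w_sum = 0.0
    per_locus = {}
    for name, (values, groups) in obs.items():
        if groups_subset is not None:
            mask = np.isin(groups, groups_subset)
            values, groups = values[mask], groups[mask]
        if len(values) < 2:
            continue
        s_total = float(np.var(values, ddof=1))
        num = den = 0.0
        for g in np.unique(groups):
            v = values[groups == g]
            if len(v) >= 2:
                num += (len(v) - 1) * float(np.var(v, ddof=1))
                den += len(v) - 1
        if den == 0:
            continue
        s_within = num / den
        w = float(len(values))
        s_tot_sum += w * s_total
        s_w_sum += w * s_within
        w_sum += w
        per_locus[name] = (s_total - s_within) / s_total if s_total > 0 else 0.0
    if w_sum == 0 or s_tot_sum == 0:
        return 0.0, pd.Series(per_locus, dtype=float)
    s_bar = s_tot_sum / w_sum
    s_w_bar = s_w_sum / w_sum
    value = (s_bar - s_w_bar) / s_bar
    return float(np.clip(value, 0.0, 1.0)), pd.Series(per_locus, dtype=float)


def rst(dataset: MicrosatDataset, grouping="population") -> RstResult:
    """Slatkin-style R_ST from presence-weighted allele-size variances.

    ``grouping`` is "population" or a mapping population id -> group label.
    Per locus, S_bar is the total allele-size variance (repeat units) and
    S_W the weighted mean within-group variance; loci are combined weighted
    by observation count and R_ST = (S_bar - S_W) / S_bar, clipped to
    [0, 1].  A delete-one-locus jackknife gives the standard error.
    """
    if grouping == "population":
        group_of = {p: p for p in dataset.population_ids}
    elif isinstance(grouping, dict):
        group_of = dict(grouping)
    else:
        raise ValueError("grouping must be 'population' or a mapping")
    group_labels = sorted(set(group_of.values()))
    if len(group_labels) < 2:
        raise ValueError("need >= 2 groups")

    obs = _locus_observations(dataset, group_of)
    overall, per_locus = _rst_from_obs(obs)
    if per_locus.empty or (per_locus == 0).all() and overall == 0:
        if all(len(np.unique(v)) <= 1 for v, _ in obs.values()):
            warnings.warn("monomorphic dataset: R_ST set to 0")

    loci = list(obs)
    if len(loci) > 1:
        pseudo = []
        for drop in loci:
            sub = {k: v for k, v in obs.items() if k != drop}
            pseudo.append(_rst_from_obs(sub)[0])
        pseudo = np.asarray(pseudo)
        jk_se = float(np.sqrt((len(loci) - 1) / len(loci) * np.sum((pseudo - pseudo.mean()) ** 2)))
    else:
        jk_se = float("nan")

    n = len(group_labels)
    pair = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        value, _ = _rst_from_obs(obs, groups_subset=[group_labels[i], group_labels[j]])
        pair[i, j] = pair[j, i] = value
    return RstResult(overall, per_locus, DistanceMatrix(group_labels, pair), jk_se, group_of)


# ---------------------------------------------------------------------------
# contrast classification


@dataclass
class DifferentiationReport:
    """P_ST vs R_ST contrast: per-trait classification and h2 screening."""

    table: pd.DataFrame
    rst_overall: float
    tolerance: float
    h2_threshold: float

    @property
    def classification(self) -> dict:
        return dict(self.table["classification"])

    @property
    def local_adaptation(self) -> list:
        return list(self.table.index[self.table["local_adaptation"]])


def pst_rst_contrast(
    pst_by_trait: dict,
    h2_by_trait: dict,
    rst_overall: float,
    tolerance: float = 0.03,
    h2_threshold: float = 0.25,
) -> DifferentiationReport:
    """Classify each trait against the neutral marker baseline.

    P_ST > R_ST + tolerance -> divergent_selection;
    |P_ST - R_ST| <= tolerance -> drift_consistent;
    P_ST < R_ST - tolerance -> uniform_selection.
    Traits with h2 >= ``h2_threshold`` are flagged as local-adaptation
    candidates.
    """
    if not pst_by_trait:
        raise ValueError("need at least one trait")
    rows = []
    for trait, p in pst_by_trait.items():
        if p > rst_overall + tolerance:
            label = "divergent_selection"
        elif p < rst_overall - tolerance:
            label = "uniform_selection"
        else:
            label = "drift_consistent"
        h2 = h2_by_trait.get(trait, float("nan"))
        rows.append(
            {
                "trait": trait,
                "P_ST": p,
                "h2": h2,
                "classification": label,
                "local_adaptation": bool(np.isfinite(h2) and h2 >= h2_threshold),
            }
        )
    table = pd.DataFrame(rows).set_index("trait")
    return DifferentiationReport(table, rst_overall, tolerance, h2_threshold)


# ---------------------------------------------------------------------------
# Duncan's multiple range test


def _duncan_lsr(span: int, df: int, alpha: float, scale: float) -> float:
    protection = 1.0 - (1.0 - alpha) ** (span - 1)
    q = stats.studentized_range.ppf(1.0 - protection, span, df)
    return float(q * scale)


def duncan_mrt(phenotypes, trait: str, alpha: float = 0.05) -> pd.DataFrame:
    """Duncan's multiple range test with a compact letter display.

    Populations sharing a letter do not differ significantly.  Uses the
    pooled within-population mean square and the harmonic mean group size
    for unbalanced data.
    """
    frame = _as_frame(phenotypes)
    data, _, _ = _collapse_replicates(frame, trait)  # plant means, no pseudo-replication
    groups = data.groupby("population", sort=False)[trait]
    means = groups.mean()
    counts = groups.size()
    if len(means) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 populations with >= 2 plants each")
    ss_within = float(((data[trait] - data["population"].map(means)) ** 2).sum())
    df_within = int((counts - 1).sum())
    ms_within = ss_within / df_within
    n_h = len(counts) / float((1.0 / counts).sum())

    order = means.sort_values(ascending=False)
    k = len(order)
    values = order.to_numpy()

    homogeneous: set[tuple[int, int]] = set()
    if ms_within == 0:
        # zero pooled variance: only exactly equal means are homogeneous
        i = 0
        while i < k:
            j = i
            while j + 1 < k and values[j + 1] == values[i]:
                j += 1
            if j > i:
                homogeneous.add((i, j))
            i = j + 1
    else:
        scale = float(np.sqrt(ms_within / n_h))
        lsr = {p: _duncan_lsr(p, df_within, alpha, scale) for p in range(2, k + 1)}

        def probe(i: int, j: int) -> None:
            if i >= j:
                return
            if values[i] - values[j] <= lsr[j - i + 1]:
                homogeneous.add((i, j))
            else:
                probe(i + 1, j)
                probe(i, j - 1)

        probe(0, k - 1)

    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in homogeneous)
    ]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    for i in range(k):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()

    letters = {pop: "" for pop in order.index}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, (i, j) in zip(alphabet, maximal):
        for idx in range(i, j + 1):
            letters[order.index[idx]] += letter

    return pd.DataFrame(
        {
            "mean": order,
            "n": counts.reindex(order.index),
            "letters": pd.Series(letters).reindex(order.index),
        }
    )


# ---------------------------------------------------------------------------
# combined model


class DifferentiationModel:
    """Joint phenotypic/genetic differentiation analysis.

    Decomposes every trait, computes R_ST from the genotype dataset (if
    given) and classifies each trait's P_ST against it.
    """

    def __init__(self, phenotypes, genotypes: MicrosatDataset | None = None,
                 traits=None):
        self.phenotypes = _as_frame(phenotypes)
        self.genotypes = genotypes
        if traits is None:
            traits = [c for c in self.phenotypes.columns if c not in FACTOR_COLUMNS]
        self.traits = list(traits)

    def fit(
        self,
        method: str = "reml",
        grouping="population",
        tolerance: float = 0.03,
        h2_threshold: float = 0.25,
    ) -> "DifferentiationResults":
        components = {
            t: estimate_variance_components(self.phenotypes, t, method=method)
            for t in self.traits
        }
        pst_by_trait = {t: pst(c.v_ap, c.v_wp) for t, c in components.items()}
        h2_by_trait = {t: heritability(c) for t, c in components.items()}
        rst_result = None
        report = None
        if self.genotypes is not None:
            rst_result = rst(self.genotypes, grouping=grouping)
            report = pst_rst_contrast(
                pst_by_trait, h2_by_trait, rst_result.overall, tolerance, h2_threshold
            )
        return DifferentiationResults(
            self, components, pst_by_trait, h2_by_trait, rst_result, report
        )


class DifferentiationResults:
    """Fitted differentiation analysis; ``summary()`` mirrors the published
    variance-decomposition table layout (components, P_ST, h2 per trait)."""

    def __init__(self, model, components, pst_by_trait, h2_by_trait, rst_result, report):
        self.model = model
        self.components = components
        self.pst = pst_by_trait
        self.h2 = h2_by_trait
        self.rst = rst_result
        self.report = report

    def summary(self) -> pd.DataFrame:
        cols = {}
        for trait, comp in self.components.items():
            col = comp.as_series()
            col["P_ST"] = self.pst[trait]
            col["h2"] = self.h2[trait]
            cols[trait] = col
        table = pd.DataFrame(cols)
        if self.report is not None:
            table.loc["classification"] = [
                self.report.classification[t] for t in table.columns
            ]
        return table

    def __repr__(self) -> str:
        rst_txt = f" R_ST={self.rst.overall:.3f}" if self.rst is not None else ""
        return f"<DifferentiationResults traits={len(self.pst)}{rst_txt}>"
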