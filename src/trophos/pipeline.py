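"""End-to-end analysis pipeline.

Orchestrates simulate -> isotope preprocessing -> diet indices ->
multivariate statistics -> niche geometry, writing a reproducible report
bundle of CSV tables plus a YAML manifest.  Given the same configuration
and seed the bundle is byte-identical across runs.

Statistical design mirrors the study: the interspecific tests use a
two-factor mixed model (species fixed, area random nested in species,
permutation of residuals under a reduced model); the intraspecific tests
use a one-way design with area fixed (unrestricted permutation of raw
data).  Depth stratum is carried as a column but never tested — the
sampling is too unbalanced for a symmetrical fixed design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diet_indices import biomass_matrix, diet_index_table, shannon_diversity
from .exceptions import ConfigurationError, TrophosError
from .isotope_processing import correct_samples, correlation_table
from .multivariate_stats import (
    DistanceMatrix,
    braycurtis_matrix,
    cap,
    euclidean_matrix,
    pairwise_permanova,
    permanova_nested,
    permanova_oneway,
    permdisp,
    simper,
)
from .niche_metrics import ellipse_overlap, niche_summary, standard_ellipse
from .synthetic_data import (
    ScenarioConfig,
    SyntheticDataset,
    default_scenario,
    generate_dataset,
    read_dataset,
    write_dataset,
)
from .types import SPECIES, isotopes_to_frame, specimens_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

_ALL_STAGES = ("simulate", "isotopes", "diet", "multivariate", "niche")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    scenario: ScenarioConfig | None = None
    input_dir: Path | None = None  # read external CSVs instead of simulating
    stages: tuple[str, ...] = _ALL_STAGES
    n_perm: int = 9999
    n_draws: int = 4000
    seed: int = 42
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ConfigurationError("n_perm must be >= 99")
        if self.n_draws < 100:
            raise ConfigurationError("n_draws must be >= 100")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")


@dataclass
class PipelineReport:
    """In-memory report bundle: named tables plus the run manifest."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in sorted(self.tables.items()):
            tab.to_csv(out / f"{name}.csv", float_format="%.10g")
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)


def _sub_seed(root: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=root, spawn_key=(100 + k,))
               .generate_state(1)[0] % (2**31 - 1))


def _flatten_permanova(results: list[tuple[dict, pd.DataFrame]]) -> pd.DataFrame:
    rows = []
    for meta, tab in results:
        for term, r in tab.iterrows():
            rows.append({**meta, "term": term, **r.to_dict()})
    return pd.DataFrame(rows).set_index(
        ["analysis", "design", "group", "term"]
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run all configured stages and write the report bundle.

    Non-fatal stage errors (degenerate designs, empty groups) are caught,
    logged into the manifest under ``skipped``, and the pipeline continues.
    """
    config.validate()
    report = PipelineReport()
    skipped: list[dict] = []

    # ---- data -------------------------------------------------------------
    if config.input_dir is not None:
        dataset = read_dataset(config.input_dir)
    else:
        scenario = config.scenario or default_scenario(seed=config.seed)
        dataset = generate_dataset(scenario)
    spec_df = specimens_to_frame(dataset.specimens)
    if "simulate" in config.stages:
        write_dataset(dataset, config.out_dir)

    corrected = correct_samples(dataset.isotopes)
    iso_df = isotopes_to_frame(corrected)

    def _stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        try:
            fn()
        except TrophosError as exc:
            logger.warning("stage %s skipped: %s", name, exc)
            skipped.append({"stage": name, "reason": str(exc)})

    _stage("isotopes", lambda: _isotope_stage(report, spec_df, iso_df))
    _stage("diet", lambda: _diet_stage(report, dataset, spec_df, config, skipped))
    _stage("multivariate",
           lambda: _multivariate_stage(report, dataset, spec_df, iso_df,
                                       config, skipped))
    _stage("niche", lambda: _niche_stage(report, spec_df, iso_df, config))

    report.manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_draws": config.n_draws,
        "alpha": config.alpha,
        "stages": list(config.stages),
        "n_specimens": len(dataset.specimens),
        "scenario": dataset.config.to_dict(),
        "skipped": skipped,
        "tables": sorted(report.tables),
    }
    report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# stages


def _isotope_stage(report, spec_df, iso_df) -> None:
    report.tables["isotopes_corrected"] = iso_df.set_index("specimen_id")
    corr = correlation_table(spec_df, iso_df)
    report.tables["tl_correlations"] = corr.set_index(["species", "isotope"])


def _specimen_stomach_frame(dataset, spec_df) -> pd.DataFrame:
    rows = []
    for spec, st in zip(dataset.specimens, dataset.stomachs):
        try:
            hprime = np.nan if st.empty or not st.prey else shannon_diversity(st)
        except TrophosError:
            hprime = np.nan
        rows.append(
            {"specimen_id": spec.id, "species": spec.species, "area": spec.area,
             "stratum": spec.stratum, "fullness_pct": st.fullness,
             "empty": st.empty, "hprime": hprime}
        )
    return pd.DataFrame(rows)


def _univariate_tests(values_df, col, config, seed0, skipped) -> list:
    """Nested (species/area) and per-species one-way tests on one variable."""
    results = []
    sub = values_df.dropna(subset=[col])
    dm = euclidean_matrix(sub[col].to_numpy(), labels=sub["specimen_id"])
    try:
        nested = permanova_nested(
            dm, sub["species"], sub["area"],
            n_perm=config.n_perm, seed=seed0,
        )
        results.append(
            ({"analysis": col, "design": "nested", "group": "all"}, nested.table)
        )
    except TrophosError as exc:
        skipped.append({"stage": f"univariate:{col}", "reason": str(exc)})
    for k, sp in enumerate(SPECIES):
        grp = sub[sub["species"] == sp]
        if grp.empty:
            continue
        dm_sp = euclidean_matrix(grp[col].to_numpy(), labels=grp["specimen_id"])
        try:
            one = permanova_oneway(
                dm_sp, grp["area"], n_perm=config.n_perm,
                seed=_sub_seed(seed0, k + 1),
            )
            results.append(
                ({"analysis": col, "design": "oneway_area", "group": sp},
                 one.table)
            )
        except TrophosError as exc:
            skipped.append(
                {"stage": f"univariate:{col}:{sp}", "reason": str(exc)}
            )
    return results


def _diet_stage(report, dataset, spec_df, config, skipped) -> None:
    per_fish = _specimen_stomach_frame(dataset, spec_df)
    report.tables["fullness_hprime"] = per_fish.set_index("specimen_id")

    results = _univariate_tests(per_fish, "fullness_pct", config,
                                _sub_seed(config.seed, 1), skipped)
    results += _univariate_tests(per_fish, "hprime", config,
                                 _sub_seed(config.seed, 2), skipped)
    report.tables["univariate_permanova"] = _flatten_permanova(results)

    by_id = {s.id: s for s in dataset.specimens}
    tabs = []
    groups = [("species", lambda s: (s.species,)),
              ("species_area", lambda s: (s.species, s.area))]
    for level, keyfn in groups:
        buckets: dict[tuple, list] = {}
        for st in dataset.stomachs:
            buckets.setdefault(keyfn(by_id[st.specimen_id]), []).append(st)
        for key in sorted(buckets):
            try:
                tab = diet_index_table(buckets[key]).reset_index()
            except TrophosError as exc:
                skipped.append(
                    {"stage": f"diet_indices:{key}", "reason": str(exc)}
                )
                continue
            tab.insert(0, "group", " / ".join(key))
            tab.insert(0, "level", level)
            tabs.append(tab)
    report.tables["diet_indices"] = pd.concat(tabs).set_index(
        ["level", "group", "taxon"]
    )


def _multivariate_stage(report, dataset, spec_df, iso_df, config, skipped) -> None:
    meta = spec_df.set_index("id")
    biomass = biomass_matrix(dataset.stomachs)

    results = []
    dm = braycurtis_matrix(biomass)
    kept = list(dm.labels)
    species = meta.loc[kept, "species"].to_numpy()
    areas = meta.loc[kept, "area"].to_numpy()

    try:
        nested = permanova_nested(dm, species, areas, n_perm=config.n_perm,
                                  seed=_sub_seed(config.seed, 10))
        results.append(
            ({"analysis": "diet_biomass", "design": "nested", "group": "all"},
             nested.table)
        )
    except TrophosError as exc:
        skipped.append({"stage": "diet_permanova_nested", "reason": str(exc)})

    for k, sp in enumerate(SPECIES):
        mask = species == sp
        if mask.sum() < 4:
            continue
        try:
            one = permanova_oneway(dm.subset(mask), areas[mask],
                                   n_perm=config.n_perm,
                                   seed=_sub_seed(config.seed, 11 + k))
            results.append(
                ({"analysis": "diet_biomass", "design": "oneway_area",
                  "group": sp}, one.table)
            )
        except TrophosError as exc:
            skipped.append({"stage": f"diet_permanova:{sp}", "reason": str(exc)})
    report.tables["diet_permanova"] = _flatten_permanova(results)

    # dispersion homogeneity between species: generalism vs specialism
    try:
        disp = permdisp(dm, species, n_perm=config.n_perm,
                        seed=_sub_seed(config.seed, 20))
        report.tables["permdisp_means"] = disp.group_means.to_frame()
        summary = pd.DataFrame(
            {"F": [disp.f_stat], "p_perm": [disp.p_perm],
             "n_perm": [disp.n_perm], "tested": [disp.tested]}
        )
        report.tables["permdisp_test"] = summary
        report.tables["permdisp_pairwise"] = disp.pairwise
    except TrophosError as exc:
        skipped.append({"stage": "permdisp", "reason": str(exc)})

    # SIMPER between species and, within species, between areas
    simper_rows = []
    for res in simper(biomass.loc[kept], species):
        tab = res.truncated.reset_index()
        tab.insert(0, "pair", f"{res.group_a} vs {res.group_b}")
        tab.insert(1, "scope", "species")
        tab["average_dissimilarity_pct"] = res.average_dissimilarity
        simper_rows.append(tab)
    for sp in SPECIES:
        mask = species == sp
        if len(set(areas[mask])) < 2:
            continue
        for res in simper(biomass.loc[kept].loc[mask], areas[mask]):
            tab = res.truncated.reset_index()
            tab.insert(0, "pair", f"{sp}: {res.group_a} vs {res.group_b}")
            tab.insert(1, "scope", "areas_within_species")
            tab["average_dissimilarity_pct"] = res.average_dissimilarity
            simper_rows.append(tab)
    report.tables["simper"] = pd.concat(simper_rows).set_index(["scope", "pair"])

    # CAP ordination for the species factor
    try:
        cap_res = cap(dm, species)
        report.tables["cap_axes"] = cap_res.axes
        report.tables["cap_summary"] = pd.DataFrame(
            {"m": [cap_res.m],
             "allocation_success_pct": [cap_res.allocation_success]}
        )
        report.tables["cap_per_group"] = cap_res.per_group_success.to_frame()
    except TrophosError as exc:
        skipped.append({"stage": "cap", "reason": str(exc)})

    # isotope PERMANOVAs on Euclidean matrices of untransformed values
    iso = iso_df.set_index("specimen_id")
    iso_meta = meta.loc[iso.index]
    iso_results = []
    pairwise_tabs = []
    analyses = {
        "d13C": iso[["d13c_corrected"]].to_numpy(),
        "d15N": iso[["d15n"]].to_numpy(),
        "d13C_d15N": iso[["d13c_corrected", "d15n"]].to_numpy(),
    }
    for k, (name, values) in enumerate(sorted(analyses.items())):
        dm_iso = euclidean_matrix(values, labels=iso.index)
        try:
            res = permanova_nested(
                dm_iso, iso_meta["species"], iso_meta["area"],
                n_perm=config.n_perm, seed=_sub_seed(config.seed, 30 + k),
            )
        except TrophosError as exc:
            skipped.append({"stage": f"isotope_permanova:{name}",
                            "reason": str(exc)})
            continue
        iso_results.append(
            ({"analysis": name, "design": "nested", "group": "all"}, res.table)
        )
        if res.p_value("fixed") < config.alpha:
            pw = _pairwise_nested(dm_iso, iso_meta["species"].to_numpy(),
                                  iso_meta["area"].to_numpy(), config,
                                  _sub_seed(config.seed, 40 + k))
            pw.insert(0, "analysis", name)
            pairwise_tabs.append(pw)
    report.tables["isotope_permanova"] = _flatten_permanova(iso_results)
    if pairwise_tabs:
        report.tables["isotope_pairwise"] = pd.concat(pairwise_tabs).set_index(
            ["analysis", "group_a", "group_b"]
        )


def _pairwise_nested(dm: DistanceMatrix, species, areas, config,
                     seed: int) -> pd.DataFrame:
    """Species pairwise comparisons under the nested scheme, restricted to
    each pair of levels; falls back to one-way when a pair has no nested
    structure left."""
    levels = sorted(set(species.tolist()))
    rng = np.random.default_rng(seed)
    rows = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            mask = (species == la) | (species == lb)
            sub = dm.subset(mask)
            sub_seed = int(rng.integers(2**31 - 1))
            try:
                res = permanova_nested(sub, species[mask], areas[mask],
                                       n_perm=config.n_perm, seed=sub_seed)
                f, p = res.pseudo_f("fixed"), res.p_value("fixed")
            except TrophosError:
                try:
                    res = permanova_oneway(sub, species[mask],
                                           n_perm=config.n_perm, seed=sub_seed)
                    f, p = res.pseudo_f("factor"), res.p_value("factor")
                except TrophosError:
                    f, p = np.nan, np.nan
            rows.append({"group_a": la, "group_b": lb, "pseudoF": f,
                         "p_perm": p, "n": int(mask.sum())})
    return pd.DataFrame(rows)


def _niche_stage(report, spec_df, iso_df, config) -> None:
    meta = spec_df.set_index("id")
    iso = iso_df.set_index("specimen_id")
    pts = iso[["d13c_corrected", "d15n"]].to_numpy()
    species = meta.loc[iso.index, "species"].to_numpy()
    areas = meta.loc[iso.index, "area"].to_numpy()

    by_species = {sp: pts[species == sp] for sp in sorted(set(species.tolist()))}
    report.tables["niche_species"] = niche_summary(
        by_species, n_draws=config.n_draws, seed=_sub_seed(config.seed, 50)
    )
    by_cell = {
        f"{sp} / {ar}": pts[(species == sp) & (areas == ar)]
        for sp in sorted(set(species.tolist()))
        for ar in sorted(set(areas[species == sp].tolist()))
    }
    report.tables["niche_species_area"] = niche_summary(
        by_cell, n_draws=config.n_draws, seed=_sub_seed(config.seed, 51)
    )

    ellipses = {}
    ell_rows = []
    for sp, p in by_species.items():
        try:
            e = standard_ellipse(p)
        except TrophosError:
            continue
        ellipses[sp] = e
        ell_rows.append(
            {"group": sp, "center_d13c": e.center[0], "center_d15n": e.center[1],
             "semi_major": e.semi_major, "semi_minor": e.semi_minor,
             "theta_rad": e.theta, "SEA": e.sea, "SEAc": e.seac, "n": e.n}
        )
    report.tables["ellipse_params"] = pd.DataFrame(ell_rows).set_index("group")

    overlap_rows = []
    names = sorted(ellipses)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ov = ellipse_overlap(ellipses[a], ellipses[b])
            overlap_rows.append(
                {"group_a": a, "group_b": b, "overlap_permil2": ov["overlap"],
                 "pct_of_a": ov["pct_of_a"], "pct_of_b": ov["pct_of_b"]}
            )
    report.tables["ellipse_overlap"] = pd.DataFrame(overlap_rows).set_index(
        ["group_a", "group_b"]
    )
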