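"""End-to-end orchestration: one config drives every analysis stage.

Stages run in method order — simulate/ingest, cohort accounting, alpha
diversity with group tests, Bray-Curtis / PCoA / PERMANOVA with tight
clusters, per-(site, season) community state clustering, and transition /
association networks — each stage reading only prior-stage outputs and
writing plain TSV (plus Newick / GEXF / GraphML) under the run directory.
A serialized copy of the validated config and a run log land beside the
outputs, and all randomness derives from the single config seed, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, diversity, ordination, transitions
from .core import (
    SEASONS,
    SITES,
    AbundanceTable,
    DataError,
    RelativeAbundanceTable,
    SampleMetadata,
    TaxonomyTable,
    aggregate_by_rank,
    logger,
    read_tables,
    to_relative,
    top_taxa,
    write_tables,
)
from .simulate import GroundTruth, simulate_cohort, study_like_spec, write_ground_truth


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: str
    seed: int = 0
    # input: either the three TSV paths, or simulate=True
    simulate: bool = True
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    analysis_unit: str = "genus"  # or "asv"
    top_n_taxa: int = 26
    permutations: int = 999
    k_min: int = 2
    k_max: int = 8
    distance_kind: str = "euclidean"
    n_boot: int = 0
    alpha: float = 0.05
    tight_k_neighbors: int = 5
    tight_density_quantile: float = 0.6
    tight_linking_radius_quantile: float = 0.25
    rarefaction_depth: int | None = None
    make_plots: bool = True

    def validate(self) -> None:
        if self.analysis_unit not in ("genus", "asv"):
            raise DataError("analysis_unit must be 'genus' or 'asv'")
        if self.distance_kind not in clustering.DISTANCE_KINDS:
            raise DataError(f"distance_kind must be in {clustering.DISTANCE_KINDS}")
        if not self.simulate:
            for name in ("counts_path", "taxonomy_path", "metadata_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise DataError(f"{name} missing or does not exist: {p}")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise DataError("need 2 <= k_min <= k_max")
        if self.permutations < 1:
            raise DataError("permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cohort accounting
# ---------------------------------------------------------------------------

def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention used for printed percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int) -> float:
    """100 * count / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise DataError("percentage denominator is zero")
    return round_half_up(100.0 * count / denominator, 1)


@dataclass
class CohortReport:
    """Subject and sample accounting over every metadata stratum.

    ``subjects_by_*`` count distinct subjects; ``samples_by_*`` count
    samples.  Percentages recompute exactly from the integer counts with
    round-half-up at one decimal.
    """

    n_subjects: int
    n_samples: int
    subjects_by_sex: pd.DataFrame
    subjects_by_age: pd.DataFrame
    subjects_by_grade: pd.DataFrame
    samples_by_group: pd.DataFrame  # group x (total + per-season columns)
    complete_coverage: pd.DataFrame  # per site: subjects present all seasons

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "subjects_by_sex": self.subjects_by_sex,
            "subjects_by_age": self.subjects_by_age,
            "subjects_by_grade": self.subjects_by_grade,
            "samples_by_group": self.samples_by_group,
            "complete_coverage": self.complete_coverage,
        }


def _subject_breakdown(subjects: pd.DataFrame, col: str) -> pd.DataFrame:
    counts = subjects[col].value_counts().sort_index()
    total = int(counts.sum())
    out = pd.DataFrame({
        "count": counts.astype(int),
        "percent": [percentage(int(c), total) for c in counts],
    })
    out.index.name = col
    return out


def cohort_report(metadata: SampleMetadata) -> CohortReport:
    """Tabulate subjects and samples by sex, age, grade, site and season."""
    t = metadata.table
    subjects = t.drop_duplicates("subject_id").set_index("subject_id")
    n_subjects = len(subjects)
    n_samples = len(t)

    seasons = [s for s in SEASONS if s in set(t["season"])]

    def season_counts(mask) -> list[int]:
        sub = t[mask] if mask is not None else t
        return [int(len(sub))] + [int((sub["season"] == s).sum()) for s in seasons]

    groups: dict[str, pd.Series | None] = {"All samples": None}
    for sex in ("female", "male"):
        groups[sex.capitalize()] = t["sex"] == sex
    for site in SITES:
        if (t["site"] == site).any():
            groups[site.capitalize()] = t["site"] == site
    for sex in ("female", "male"):
        for site in SITES:
            mask = (t["sex"] == sex) & (t["site"] == site)
            if mask.any():
                groups[f"{sex.capitalize()} {site}"] = mask
    samples_by_group = pd.DataFrame(
        {name: season_counts(mask) for name, mask in groups.items()},
        index=["total"] + list(seasons),
    ).T
    samples_by_group.index.name = "group"

    cov_rows = []
    for site in SITES:
        sub = t[t["site"] == site]
        if not len(sub):
            continue
        per_subject = sub.groupby("subject_id")["season"].nunique()
        complete = int((per_subject == len(SEASONS)).sum())
        cov_rows.append({
            "site": site,
            "subjects_sampled": int(per_subject.size),
            "complete_three_season": complete,
            "percent_of_enrolled": percentage(complete, n_subjects),
        })
    any_site = t.groupby("subject_id")["season"].nunique()
    cov_rows.append({
        "site": "any",
        "subjects_sampled": int(any_site.size),
        "complete_three_season": int((any_site == len(SEASONS)).sum()),
        "percent_of_enrolled": percentage(
            int((any_site == len(SEASONS)).sum()), n_subjects),
    })
    coverage = pd.DataFrame(cov_rows).set_index("site")

    return CohortReport(
        n_subjects=n_subjects,
        n_samples=n_samples,
        subjects_by_sex=_subject_breakdown(subjects.reset_index(), "sex"),
        subjects_by_age=_subject_breakdown(subjects.reset_index(), "age"),
        subjects_by_grade=_subject_breakdown(subjects.reset_index(), "grade"),
        samples_by_group=samples_by_group,
        complete_coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Stage runner
# ---------------------------------------------------------------------------

def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as e:
                raise DataError(f"stage {name!r} failed: {e}") from e
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapped
    return deco


def _derive_seed(base: int, label: str) -> int:
    h = hashlib.sha256(f"{base}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = logging.FileHandler(out / "run.log", mode="w")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_file)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        table, taxonomy, metadata, truth = _load_stage(config, out)
        rel = _prepare_stage(config, table, taxonomy, out)
        _report_stage(metadata, out)
        _diversity_stage(config, table, taxonomy, metadata, out)
        ordn = _ordination_stage(config, rel, metadata, out)
        solutions, enrichments = _clustering_stage(config, rel, metadata, out)
        _transitions_stage(config, rel, metadata, solutions, out)
        if config.make_plots:
            _plot_stage(ordn, metadata, solutions, out)
    finally:
        logger.removeHandler(log_file)
        log_file.close()
    return out


@_stage("load")
def _load_stage(config, out):
    if config.simulate:
        spec = dataclasses.replace(study_like_spec(), seed=_derive_seed(config.seed, "cohort"))
        table, taxonomy, metadata, truth = simulate_cohort(spec)
        write_tables(table, taxonomy, metadata, out)
        write_ground_truth(truth, out / "ground_truth.tsv")
    else:
        table, taxonomy, metadata = read_tables(
            config.counts_path, config.taxonomy_path, config.metadata_path)
        truth = None
    return table, taxonomy, metadata, truth


@_stage("prepare")
def _prepare_stage(config, table, taxonomy, out) -> RelativeAbundanceTable:
    unit = table if config.analysis_unit == "asv" else aggregate_by_rank(
        table, taxonomy, "genus")
    rel = to_relative(unit)
    rel.fractions.to_csv(out / f"relative_abundance_{config.analysis_unit}.tsv", sep="\t")
    top = top_taxa(rel, min(config.top_n_taxa, len(rel.taxon_ids)))
    top.fractions.to_csv(out / "top_taxa.tsv", sep="\t")
    return rel


@_stage("report")
def _report_stage(metadata, out):
    report = cohort_report(metadata)
    for name, frame in report.tables().items():
        frame.to_csv(out / f"cohort_{name}.tsv", sep="\t")
    return report


@_stage("diversity")
def _diversity_stage(config, table, taxonomy, metadata, out):
    counts = table if config.analysis_unit == "asv" else aggregate_by_rank(
        table, taxonomy, "genus")
    if config.rarefaction_depth:
        from .core import rarefy
        counts = rarefy(counts, config.rarefaction_depth,
                        seed=_derive_seed(config.seed, "rarefy"))
    alpha = diversity.alpha_diversity(counts)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    frames = []
    meta = metadata.subset(list(alpha.index))
    for index in ("chao1", "shannon", "simpson"):
        frames.append(diversity.results_frame(
            diversity.compare_alpha(alpha, meta, index)))
    pd.concat(frames, ignore_index=True).to_csv(
        out / "alpha_group_tests.tsv", sep="\t", index=False)
    return alpha


@_stage("ordination")
def _ordination_stage(config, rel, metadata, out):
    dm = ordination.bray_curtis(rel)
    dm.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
    ordn = ordination.pcoa(dm)
    ordn.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame({
        "eigenvalue": ordn.eigenvalues,
    }).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    meta = metadata.table.loc[rel.sample_ids]
    perm_rows = []
    for factor in ("site", "season"):
        if meta[factor].nunique() >= 2 and meta[factor].value_counts().min() >= 2:
            res = ordination.permanova(
                dm, meta[factor], n_permutations=config.permutations,
                seed=_derive_seed(config.seed, f"permanova:{factor}"),
                factor=factor)
            perm_rows.append({
                "factor": res.factor, "pseudo_F": res.pseudo_F,
                "R_squared": res.R_squared, "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            })
    pd.DataFrame(perm_rows).to_csv(out / "permanova.tsv", sep="\t", index=False)
    tight_rows = []
    for site in SITES:
        ids = [s for s in rel.sample_ids if meta.loc[s, "site"] == site]
        if len(ids) <= max(4, config.tight_k_neighbors):
            continue
        sub = ordination.pcoa(dm.subset(ids))
        if sub.coordinates.shape[1] < 2:
            continue
        tc = ordination.extract_tight_clusters(
            sub, k_neighbors=config.tight_k_neighbors,
            density_quantile=config.tight_density_quantile,
            linking_radius_quantile=config.tight_linking_radius_quantile,
            site=site)
        tight_rows.extend({"site": site, "sample_id": s} for s in tc.members)
    pd.DataFrame(tight_rows, columns=["site", "sample_id"]).to_csv(
        out / "tight_clusters.tsv", sep="\t", index=False)
    return ordn


@_stage("clustering")
def _clustering_stage(config, rel, metadata, out):
    meta = metadata.table.loc[rel.sample_ids]
    solutions, enrichments = [], []
    sil_rows, label_rows = [], []
    for site in SITES:
        for season in SEASONS:
            ids = sorted(meta.index[(meta["site"] == site) & (meta["season"] == season)])
            if len(ids) < max(4, config.k_min + 2):
                continue
            sub = rel.subset(ids)
            dend = clustering.ward_cluster(sub, config.distance_kind)
            k_max = min(config.k_max, len(ids) - 1)
            sol = clustering.select_k(
                dend, sub, k_min=config.k_min, k_max=k_max,
                distance_kind=config.distance_kind, stratum=(site, season))
            if config.n_boot:
                sol.bootstrap_support = clustering.bootstrap_support(
                    sub, dend, n_boot=config.n_boot,
                    seed=_derive_seed(config.seed, f"boot:{site}:{season}"),
                    distance_kind=config.distance_kind)
            enr = clustering.enrich_clusters(sub, sol, alpha=config.alpha)
            enr.insert(0, "season", season)
            enr.insert(0, "site", site)
            solutions.append(sol)
            enrichments.append(enr)
            (out / f"dendrogram_{site}_{season}.nwk").write_text(dend.to_newick())
            for k, s in sol.silhouette_by_k.items():
                sil_rows.append({"site": site, "season": season, "k": k,
                                 "mean_silhouette": s, "chosen": k == sol.k})
            for sid, lab in sol.labels.items():
                label_rows.append({"site": site, "season": season,
                                   "sample_id": sid, "cluster": lab})
    families = clustering.assign_family_names(solutions, enrichments)
    fam_frame = pd.DataFrame(
        [{"site": k[0], "season": k[1], "cluster": k[2], "family": v}
         for k, v in families.items()])
    fam_frame.to_csv(out / "cluster_families.tsv", sep="\t", index=False)
    pd.DataFrame(label_rows).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
    pd.DataFrame(sil_rows).to_csv(out / "silhouette_trace.tsv", sep="\t", index=False)
    if enrichments:
        pd.concat(enrichments, ignore_index=True).to_csv(
            out / "cluster_enrichment.tsv", sep="\t", index=False)
    return solutions, enrichments


@_stage("transitions")
def _transitions_stage(config, rel, metadata, solutions, out):
    by_stratum = {(s.site, s.season): s for s in solutions}
    result_frames = []
    for site in SITES:
        for a, b in zip(SEASONS[:-1], SEASONS[1:]):
            if (site, a) not in by_stratum or (site, b) not in by_stratum:
                continue
            tt = transitions.build_transition_table(
                by_stratum[(site, a)], by_stratum[(site, b)], metadata)
            tt.matrix.to_csv(out / f"transition_matrix_{site}_{a}_{b}.tsv", sep="\t")
            res = transitions.test_transitions(tt, alpha=config.alpha)
            res.insert(0, "season_pair", f"{a}->{b}")
            res.insert(0, "site", site)
            result_frames.append(res)
            g = transitions.build_transition_network(
                tt, res.drop(columns=["site", "season_pair"]))
            transitions.write_network(
                g, gexf_path=out / f"transition_network_{site}_{a}_{b}.gexf",
                graphml_path=out / f"transition_network_{site}_{a}_{b}.graphml")
    if result_frames:
        pd.concat(result_frames, ignore_index=True).to_csv(
            out / "transition_tests.tsv", sep="\t", index=False)
    meta = metadata.table.loc[rel.sample_ids]
    assoc_frames = []
    for site in SITES:
        ids = [s for s in rel.sample_ids if meta.loc[s, "site"] == site]
        if len(ids) < 10:
            continue
        edges, g, hub = transitions.taxon_association_network(
            rel.subset(ids), site=site)
        edges.insert(0, "site", site)
        edges["hub"] = hub
        assoc_frames.append(edges)
        transitions.write_network(
            g, gexf_path=out / f"association_network_{site}.gexf",
            graphml_path=out / f"association_network_{site}.graphml")
    if assoc_frames:
        pd.concat(assoc_frames, ignore_index=True).to_csv(
            out / "taxon_associations.tsv", sep="\t", index=False)


@_stage("plots")
def _plot_stage(ordn, metadata, solutions, out):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    meta = metadata.table
    fig, ax = plt.subplots(figsize=(6, 5))
    coords = ordn.coordinates
    for site, marker in zip(SITES, "ox"):
        ids = [s for s in coords.index if meta.loc[s, "site"] == site]
        if not ids:
            continue
        ax.scatter(coords.loc[ids, "PC1"],
                   coords.loc[ids, "PC2"] if "PC2" in coords else 0,
                   s=12, marker=marker, label=site, alpha=0.6)
    prop = ordn.proportion_explained
    ax.set_xlabel(f"PC1 ({prop[0] * 100:.1f}%)" if len(prop) else "PC1")
    ax.set_ylabel(f"PC2 ({prop[1] * 100:.1f}%)" if len(prop) > 1 else "PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pcoa_site.png", dpi=120)
    plt.close(fig)

    for sol in solutions:
        fig, ax = plt.subplots(figsize=(8, 4))
        scipy_dendrogram(sol.dendrogram.linkage, labels=sol.dendrogram.leaf_ids,
                         ax=ax, leaf_font_size=5)
        ax.set_title(f"{sol.site} / {sol.season} (k={sol.k})")
        fig.tight_layout()
        fig.savefig(out / f"dendrogram_{sol.site}_{sol.season}.png", dpi=120)
        plt.close(fig)
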