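"""Synthetic longitudinal cohort generator with planted ground truth.

Emulates a two-site (oral / nasopharyngeal), three-season (autumn, winter,
spring) school cohort: each subject carries a latent community *archetype*
per site that evolves as a Markov chain across seasons; contributed samples
draw genus proportions from the archetype's Dirichlet and integer counts
from a multinomial at a lognormal library size.  This
Dirichlet-multinomial-with-lognormal-depth model is the standard
overdispersed description of 16S count data.

The generator exists so that every downstream stage — diversity contrasts,
ordination, community state clustering, transition testing — can be checked
against known ground truth (archetype labels, transition matrices, planted
enrichments) at study-like sample sizes and sparsity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    RANKS,
    SEASONS,
    SEXES,
    SITES,
    AbundanceTable,
    DataError,
    SampleMetadata,
    TaxonomyTable,
)

_MIX_TOL = 1e-9

# Plausible higher-rank lineage per panel genus (phylum, order, family).
GENUS_LINEAGE: dict[str, tuple[str, str, str]] = {
    "Streptococcus": ("Firmicutes", "Lactobacillales", "Streptococcaceae"),
    "Moraxella": ("Proteobacteria", "Pseudomonadales", "Moraxellaceae"),
    "Proteus": ("Proteobacteria", "Enterobacterales", "Morganellaceae"),
    "Neisseria": ("Proteobacteria", "Neisseriales", "Neisseriaceae"),
    "Haemophilus": ("Proteobacteria", "Pasteurellales", "Pasteurellaceae"),
    "Staphylococcus": ("Firmicutes", "Bacillales", "Staphylococcaceae"),
    "Prevotella": ("Bacteroidota", "Bacteroidales", "Prevotellaceae"),
    "Rothia": ("Actinobacteriota", "Micrococcales", "Micrococcaceae"),
    "Herbaspirillum": ("Proteobacteria", "Burkholderiales", "Oxalobacteraceae"),
    "Phyllobacterium": ("Proteobacteria", "Hyphomicrobiales", "Phyllobacteriaceae"),
    "Kocuria": ("Actinobacteriota", "Micrococcales", "Micrococcaceae"),
    "Tardiphaga": ("Proteobacteria", "Hyphomicrobiales", "Bradyrhizobiaceae"),
    "Corynebacterium": ("Actinobacteriota", "Mycobacteriales", "Corynebacteriaceae"),
    "Dolosigranulum": ("Firmicutes", "Lactobacillales", "Carnobacteriaceae"),
    "Fusobacterium": ("Fusobacteriota", "Fusobacteriales", "Fusobacteriaceae"),
    "Veillonella": ("Firmicutes", "Veillonellales", "Veillonellaceae"),
}

#: Subject-age distribution of the emulated cohort (years 4..13); the counts
#: mirror the enrolled-population breakdown the generator targets.
AGE_COUNTS = {4: 4, 5: 12, 6: 18, 7: 12, 8: 10, 9: 16, 10: 29, 11: 5, 12: 12, 13: 1}
#: Female fraction among enrolled subjects.
FEMALE_FRACTION = 57 / 119

GRADES = (
    "Pre-kindergarten", "Kindergarten", "1st grade", "2nd grade", "3rd grade",
    "4th grade", "5th grade", "6th grade", "7th grade",
)


@dataclass
class ArchetypeSpec:
    """One community state: a Dirichlet over genera with a dominant genus.

    ``dominance_boost`` multiplies the dominant genus's concentration, so
    the archetype's expected composition is the boosted vector normalized.
    """

    name: str
    base_weights: Mapping[str, float]
    dominant_genus: str
    dominance_boost: float = 1.0

    def concentrations(self, genera: Sequence[str]) -> np.ndarray:
        alpha = np.array([float(self.base_weights.get(g, 0.0)) for g in genera])
        if self.dominant_genus not in genera:
            raise DataError(
                f"dominant genus {self.dominant_genus!r} not in genus panel"
            )
        alpha[list(genera).index(self.dominant_genus)] *= self.dominance_boost
        if np.any(alpha <= 0):
            bad = [g for g, a in zip(genera, alpha) if a <= 0]
            raise DataError(f"non-positive Dirichlet concentration for {bad}")
        return alpha

    def mean_composition(self, genera: Sequence[str]) -> pd.Series:
        a = self.concentrations(genera)
        return pd.Series(a / a.sum(), index=list(genera))


@dataclass
class CohortSpec:
    """Full description of a simulated cohort.

    ``initial_mixture`` and each row of every transition matrix must sum to
    one; ``participation_prob`` gives, per site, the probability that a
    subject contributes a sample in each season.
    """

    n_subjects: int
    genera: Sequence[str]
    seasons: Sequence[str] = SEASONS
    sites: Sequence[str] = SITES
    archetypes_per_site: Mapping[str, Sequence[ArchetypeSpec]] = field(default_factory=dict)
    initial_mixture: Mapping[str, Sequence[float]] = field(default_factory=dict)
    transition_matrices: Mapping[str, Sequence[np.ndarray]] = field(default_factory=dict)
    participation_prob: Mapping[str, Sequence[float]] = field(default_factory=dict)
    library_size_log_mean: float = np.log(30_000.0)
    library_size_log_sd: float = 0.5
    asvs_per_genus: int = 2
    #: initial-mixture multiplier for Moraxella-dominant archetypes in
    #: subjects aged <= young_age_max (1.0 disables the tilt)
    young_moraxella_tilt: float = 1.0
    young_age_max: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise DataError("n_subjects must be >= 1")
        for s in self.seasons:
            if s not in SEASONS:
                raise DataError(f"unknown season {s!r}")
        for site in self.sites:
            if site not in SITES:
                raise DataError(f"unknown site {site!r}")
            arch = list(self.archetypes_per_site[site])
            k = len(arch)
            for a in arch:
                a.concentrations(self.genera)  # raises on degenerate Dirichlet
            mix = np.asarray(self.initial_mixture[site], dtype=float)
            if mix.shape != (k,) or abs(mix.sum() - 1.0) > _MIX_TOL or mix.min() < 0:
                raise DataError(f"{site}: initial mixture is not a probability vector")
            mats = [np.asarray(m, dtype=float) for m in self.transition_matrices[site]]
            if len(mats) != len(self.seasons) - 1:
                raise DataError(f"{site}: need one transition matrix per season pair")
            for m in mats:
                if m.shape != (k, k) or m.min() < 0 or np.any(
                    np.abs(m.sum(axis=1) - 1.0) > _MIX_TOL
                ):
                    raise DataError(f"{site}: transition matrix rows must sum to 1")
            part = np.asarray(self.participation_prob[site], dtype=float)
            if part.shape != (len(self.seasons),) or part.min() < 0 or part.max() > 1:
                raise DataError(f"{site}: participation_prob must be per-season in [0,1]")

    def archetype_names(self, site: str) -> list[str]:
        return [a.name for a in self.archetypes_per_site[site]]


@dataclass
class GroundTruth:
    """Latent state of one simulated cohort.

    ``trajectories`` holds one row per (subject, site, season) with the true
    archetype and, when the subject contributed a sample, its id and the
    drawn library size.
    """

    trajectories: pd.DataFrame

    def sampled(self) -> pd.DataFrame:
        return self.trajectories[self.trajectories["sample_id"] != ""]

    def archetype_of(self) -> pd.Series:
        """sample_id -> true archetype for contributed samples."""
        s = self.sampled()
        return pd.Series(s["archetype"].to_numpy(), index=s["sample_id"].to_numpy())


def _lineage(genus: str) -> tuple[str, str, str]:
    if genus in GENUS_LINEAGE:
        return GENUS_LINEAGE[genus]
    return (f"{genus}_phylum", f"{genus}_order", f"{genus}_family")


def _build_taxonomy(genera: Sequence[str], asvs_per_genus: int) -> tuple[TaxonomyTable, list[str], np.ndarray]:
    """ASV panel: each genus split over `asvs_per_genus` ASVs with fixed weights."""
    split = np.array([0.7, 0.2, 0.1][:asvs_per_genus])
    split = split / split.sum()
    asv_ids, rows, genus_index = [], [], []
    for gi, g in enumerate(genera):
        phylum, order, family = _lineage(g)
        for j in range(asvs_per_genus):
            asv_ids.append(f"ASV_{g}_{j + 1}")
            rows.append((phylum, order, family, g))
            genus_index.append(gi)
    tax = TaxonomyTable(
        pd.DataFrame(rows, index=asv_ids, columns=list(RANKS))
    )
    return tax, asv_ids, split


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[AbundanceTable, TaxonomyTable, SampleMetadata, GroundTruth]:
    """Draw one cohort: latent trajectories, participation, counts, metadata.

    Fully reproducible for a fixed ``spec.seed``; two runs with the same
    spec are bit-identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genera = list(spec.genera)
    taxonomy, asv_ids, split = _build_taxonomy(genera, spec.asvs_per_genus)

    # --- subjects -----------------------------------------------------------
    ages_pool = np.array(sorted(AGE_COUNTS), dtype=int)
    age_p = np.array([AGE_COUNTS[a] for a in ages_pool], dtype=float)
    age_p /= age_p.sum()
    subjects = [f"S{i + 1:03d}" for i in range(spec.n_subjects)]
    ages = rng.choice(ages_pool, size=spec.n_subjects, p=age_p)
    sexes = np.where(rng.random(spec.n_subjects) < FEMALE_FRACTION, "female", "male")
    grade_jitter = rng.choice([-1, 0, 1], size=spec.n_subjects, p=[0.15, 0.7, 0.15])
    grades = [
        GRADES[int(np.clip(a - 4 + j, 0, len(GRADES) - 1))]
        for a, j in zip(ages, grade_jitter)
    ]

    # --- latent trajectories + samples --------------------------------------
    meta_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    count_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    for site in spec.sites:
        arch = list(spec.archetypes_per_site[site])
        names = [a.name for a in arch]
        alphas = [a.concentrations(genera) for a in arch]
        mix = np.asarray(spec.initial_mixture[site], dtype=float)
        mats = [np.asarray(m, dtype=float) for m in spec.transition_matrices[site]]
        part = np.asarray(spec.participation_prob[site], dtype=float)
        mor_idx = [i for i, a in enumerate(arch) if a.dominant_genus == "Moraxella"]
        for si, subj in enumerate(subjects):
            mix_s = mix.copy()
            if spec.young_moraxella_tilt != 1.0 and ages[si] <= spec.young_age_max:
                for i in mor_idx:
                    mix_s[i] *= spec.young_moraxella_tilt
                mix_s /= mix_s.sum()
            z = rng.choice(len(arch), p=mix_s)
            states = [z]
            for m in mats:
                z = rng.choice(len(arch), p=m[z])
                states.append(z)
            for t, season in enumerate(spec.seasons):
                contributed = rng.random() < part[t]
                sid, lib = "", 0
                if contributed:
                    sid = f"{subj}_{site}_{season}"
                    lib = int(np.round(rng.lognormal(
                        spec.library_size_log_mean, spec.library_size_log_sd
                    )))
                    lib = max(lib, 100)
                    p_genus = rng.dirichlet(alphas[states[t]])
                    genus_counts = rng.multinomial(lib, p_genus)
                    asv_counts = np.concatenate([
                        rng.multinomial(c, split) for c in genus_counts
                    ])
                    sample_ids.append(sid)
                    count_rows.append(asv_counts)
                    meta_rows.append(
                        (sid, subj, site, season, int(ages[si]), sexes[si], grades[si])
                    )
                truth_rows.append(
                    (subj, site, season, names[states[t]], sid, lib)
                )

    counts = pd.DataFrame(
        np.asarray(count_rows, dtype=np.int64).reshape(len(sample_ids), len(asv_ids)),
        index=sample_ids, columns=asv_ids,
    )
    table = AbundanceTable(counts)
    metadata = SampleMetadata(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "subject_id", "site", "season", "age", "sex", "grade"],
        ).set_index("sample_id")
    )
    truth = GroundTruth(
        pd.DataFrame(
            truth_rows,
            columns=["subject_id", "site", "season", "archetype", "sample_id", "library_size"],
        )
    )
    return table, taxonomy, metadata, truth


# ---------------------------------------------------------------------------
# Packaged default cohorts
# ---------------------------------------------------------------------------

#: Background Dirichlet weights shared by all archetypes; the dominant genus
#: of each archetype is boosted to concentration ~34, yielding a dominant
#: mean share around 0.55 and total concentration ~60 (tight, well-separated
#: community states).
_BACKGROUND = {
    "Streptococcus": 6.0, "Neisseria": 3.0, "Haemophilus": 3.0, "Rothia": 2.5,
    "Prevotella": 2.0, "Moraxella": 2.0, "Staphylococcus": 1.5,
    "Herbaspirillum": 1.5, "Corynebacterium": 1.5, "Veillonella": 1.5,
    "Phyllobacterium": 1.0, "Dolosigranulum": 1.0, "Fusobacterium": 1.0,
    "Kocuria": 0.3, "Tardiphaga": 0.3, "Proteus": 0.2,
}
_DOMINANT_ALPHA = 34.0


def make_archetype(dominant: str, name: str | None = None,
                   target_alpha: float = _DOMINANT_ALPHA) -> ArchetypeSpec:
    """Archetype = shared background with one genus boosted to ``target_alpha``."""
    return ArchetypeSpec(
        name=name or dominant,
        base_weights=dict(_BACKGROUND),
        dominant_genus=dominant,
        dominance_boost=target_alpha / _BACKGROUND[dominant],
    )


def study_like_spec(seed: int = 0) -> CohortSpec:
    """The packaged default cohort: 119 subjects, two sites, three seasons.

    Community states per site are dominated by the major upper-respiratory
    genera; the autumn mixture carries a Proteus-dominant state (~27%) that
    drains toward Streptococcus/Neisseria states by spring (its spring
    occupancy is exactly zero), Streptococcus occupancy rises over the year,
    and younger subjects (<= 7 y) are tilted toward the Moraxella state.
    Per-site, per-season participation is sparse so that only ~10% of
    subjects appear in all three seasons at a site.
    """
    naso_doms = ["Streptococcus", "Moraxella", "Proteus", "Neisseria", "Haemophilus"]
    oral_doms = ["Streptococcus", "Moraxella", "Proteus", "Herbaspirillum", "Haemophilus"]
    aw = np.array([  # autumn -> winter; Proteus row drains to Strep/Neisseria
        [0.75, 0.08, 0.02, 0.10, 0.05],
        [0.25, 0.55, 0.02, 0.10, 0.08],
        [0.45, 0.05, 0.12, 0.30, 0.08],
        [0.15, 0.05, 0.01, 0.70, 0.09],
        [0.15, 0.08, 0.01, 0.08, 0.68],
    ])
    ws = np.array([  # winter -> spring; Proteus column exactly zero
        [0.80, 0.06, 0.0, 0.09, 0.05],
        [0.22, 0.58, 0.0, 0.12, 0.08],
        [0.55, 0.05, 0.0, 0.32, 0.08],
        [0.12, 0.04, 0.0, 0.75, 0.09],
        [0.14, 0.08, 0.0, 0.10, 0.68],
    ])
    return CohortSpec(
        n_subjects=119,
        genera=list(_BACKGROUND),
        seasons=SEASONS,
        sites=SITES,
        archetypes_per_site={
            "oral": [make_archetype(d) for d in oral_doms],
            "nasopharyngeal": [make_archetype(d) for d in naso_doms],
        },
        initial_mixture={
            "oral": [0.30, 0.20, 0.27, 0.13, 0.10],
            "nasopharyngeal": [0.30, 0.22, 0.27, 0.12, 0.09],
        },
        transition_matrices={"oral": [aw, ws], "nasopharyngeal": [aw, ws]},
        participation_prob={
            "oral": [0.29, 0.50, 0.59],
            "nasopharyngeal": [0.34, 0.46, 0.70],
        },
        young_moraxella_tilt=2.5,
        seed=seed,
    )


def planted_transition_spec(seed: int = 0, n_subjects: int = 119,
                            tilt: float = 0.8) -> CohortSpec:
    """Two-season, one-site cohort with one strongly enriched transition.

    Full participation, three states A/B/C; the A row of the transition
    matrix sends mass ``tilt`` to B while B and C rows are uniform, so the
    A->B ordered pair is the planted positive and every other pair is at or
    below the null.  Used for transition-test power checks at n_subjects
    paired subjects.
    """
    doms = ["Streptococcus", "Moraxella", "Neisseria"]
    rest = (1.0 - tilt) / 2.0
    m = np.array([
        [rest, tilt, rest],
        [1 / 3, 1 / 3, 1 / 3],
        [1 / 3, 1 / 3, 1 / 3],
    ])
    return CohortSpec(
        n_subjects=n_subjects,
        genera=list(_BACKGROUND),
        seasons=("autumn", "winter"),
        sites=("nasopharyngeal",),
        archetypes_per_site={"nasopharyngeal": [make_archetype(d) for d in doms]},
        initial_mixture={"nasopharyngeal": [0.4, 0.3, 0.3]},
        transition_matrices={"nasopharyngeal": [m]},
        participation_prob={"nasopharyngeal": [1.0, 1.0]},
        seed=seed,
    )


def null_transition_spec(seed: int = 0, n_subjects: int = 119) -> CohortSpec:
    """Two-season cohort whose destination state is independent of origin.

    All transition rows equal the initial mixture, so every ordered cluster
    pair is a true null for the transition test (type-I calibration).
    """
    doms = ["Streptococcus", "Moraxella", "Neisseria"]
    mix = np.array([0.4, 0.3, 0.3])
    m = np.tile(mix, (3, 1))
    return CohortSpec(
        n_subjects=n_subjects,
        genera=list(_BACKGROUND),
        seasons=("autumn", "winter"),
        sites=("nasopharyngeal",),
        archetypes_per_site={"nasopharyngeal": [make_archetype(d) for d in doms]},
        initial_mixture={"nasopharyngeal": mix.tolist()},
        transition_matrices={"nasopharyngeal": [m]},
        participation_prob={"nasopharyngeal": [1.0, 1.0]},
        seed=seed,
    )


def reseed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a new random seed."""
    return dataclasses.replace(spec, seed=seed)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.trajectories.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference cohort marginals
# ---------------------------------------------------------------------------

#: Sample counts per (sex, site) across the three seasons in the emulated
#: cohort design (total 341 samples).
REFERENCE_SAMPLE_CELLS = {
    ("female", "oral"): (17, 25, 33),
    ("male", "oral"): (17, 34, 37),
    ("female", "nasopharyngeal"): (17, 22, 41),
    ("male", "nasopharyngeal"): (23, 33, 42),
}
#: Subjects per grade level, pre-kindergarten through 7th grade.
REFERENCE_GRADE_COUNTS = (4, 14, 16, 13, 12, 15, 30, 7, 8)
REFERENCE_N_FEMALE = 57
REFERENCE_N_MALE = 62


def reference_cohort_metadata() -> SampleMetadata:
    """Synthetic metadata table reproducing the emulated cohort's marginals.

    Deterministically assembles 341 sample records over 119 subjects whose
    sex, age, grade and site-by-season sample counts match the cohort
    design's published marginal tables exactly.  The joint subject-sample
    assignment is a synthetic stand-in (round-robin within each stratum);
    only the marginals are meaningful.  Used to verify cohort-accounting
    arithmetic.
    """
    females = [f"F{i + 1:03d}" for i in range(REFERENCE_N_FEMALE)]
    males = [f"M{i + 1:03d}" for i in range(REFERENCE_N_MALE)]
    subjects = females + males
    ages = [a for a, c in sorted(AGE_COUNTS.items()) for _ in range(c)]
    grades = [g for g, c in zip(GRADES, REFERENCE_GRADE_COUNTS) for _ in range(c)]
    age_of = dict(zip(subjects, ages))
    grade_of = dict(zip(subjects, grades))
    rows = []
    cursor = {"female": 0, "male": 0}
    for (sex, site), per_season in REFERENCE_SAMPLE_CELLS.items():
        pool = females if sex == "female" else males
        for season, count in zip(SEASONS, per_season):
            # cycle through the pool so every enrolled subject is sampled at
            # least once; a cell never exceeds the pool size, so subjects
            # stay unique within each (site, season) stratum
            for _ in range(count):
                subj = pool[cursor[sex] % len(pool)]
                cursor[sex] += 1
                rows.append((
                    f"{subj}_{site}_{season}", subj, site, season,
                    age_of[subj], sex, grade_of[subj],
                ))
    frame = pd.DataFrame(
        rows,
        columns=["sample_id", "subject_id", "site", "season", "age", "sex", "grade"],
    ).set_index("sample_id")
    return SampleMetadata(frame)
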