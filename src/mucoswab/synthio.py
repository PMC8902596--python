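"""Synthetic paired swab/colon cohorts with known mucosity structure.

The generator emulates a pre-weaning piglet trial: each animal contributes a
colon (luminal) sample and a rectal swab that is a physical blend of luminal
and mucosa-adhered material. The per-animal mixing coefficient ``m_i`` — the
fraction of adhered material in the swab — is the latent quantity whose
observable proxy is the mucosity factor (the swab's paired Bray-Curtis
distance). Two cohorts ("studies") with a shared community structure but a
multiplicative per-taxon batch effect emulate independent replicate
experiments; an early-feeding (EF) treatment suppresses the dominant
adhered genus relative to control (CON).

Count noise is Dirichlet-multinomial: the mixture acts on proportions
first (the physical blend), a Dirichlet draw adds compositional
overdispersion, and a multinomial draw at fixed depth adds sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tablesio import (
    AbundanceTable,
    SampleMetadata,
    write_abundance,
    write_metadata,
)

# genera repeatedly reported as mucosa-adhered in piglet guts; the first is
# the dominant facultative anaerobe of the mucus layer
DEFAULT_MUCOSAL_TAXA = (
    "Escherichia-Shigella",
    "Actinomyces",
    "Trueperella",
    "Peptostreptococcus",
    "Anaerococcus",
    "Peptoniphilus",
    "Enterococcus",
    "Finegoldia",
)

DEFAULT_LUMINAL_TAXA = (
    "Bacteroides",
    "Lactobacillus",
    "Prevotella_9",
    "Faecalibacterium",
    "Blautia",
    "Oscillibacter",
    "Prevotellaceae_UCG-003",
    "Prevotellaceae_UCG-004",
    "Rikenellaceae_RC9_gut_group",
    "Ruminococcaceae_UCG-002",
    "Subdoligranulum",
    "Fusobacterium",
    "Megasphaera",
    "Phascolarctobacterium",
    "Alloprevotella",
    "Parabacteroides",
    "Clostridium_sensu_stricto_1",
    "Campylobacter",
    "Streptococcus",
    "Christensenellaceae_R-7_group",
)


@dataclass(frozen=True)
class CommunityProfile:
    """A relative-abundance profile over named genera."""

    taxon_ids: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)
        if len(self.taxon_ids) != p.size:
            raise ValueError("proportions length must match taxon_ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon labels")
        if np.any(p < 0):
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1 within 1e-12")

    def __getitem__(self, taxon: str) -> float:
        return float(self.proportions[self.taxon_ids.index(taxon)])


@dataclass(frozen=True)
class CohortDesign:
    """Design of a simulated two-cohort paired swab/colon experiment.

    Defaults mirror a two-experiment piglet trial: study 1 with 14 EF + 14
    CON paired animals, study 2 with 8 + 8; 60 genera of which 8 are
    mucosa-adhered with one dominant; swab mixing coefficients uniform on
    [0, 0.6]; 20 000 reads per sample with Dirichlet concentration 200.
    """

    studies: tuple[str, ...] = ("exp1", "exp2")
    n_animals_per_arm: tuple[int, ...] = (14, 8)  # per treatment, per study
    g_taxa: int = 60
    mucosal_taxa: tuple[str, ...] = DEFAULT_MUCOSAL_TAXA  # first entry dominant
    mucosity_range: tuple[float, float] = (0.0, 0.6)
    ef_suppression: float = 0.5  # multiplies the dominant adhered genus in EF
    ef_mucosity_shift: float = 0.0  # additive shift of EF animals' m_i
    batch_sigma: float = 0.25  # log-scale sd of per-taxon study effect
    depth: int = 20_000  # reads per sample
    overdispersion: float = 200.0  # Dirichlet concentration scale
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.mucosity_range
        if not (0 <= low <= high <= 1):
            raise ValueError("mucosity_range must satisfy 0 <= low <= high <= 1")
        if not (0 < self.ef_suppression <= 1):
            raise ValueError("ef_suppression must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if self.g_taxa < 10:
            raise ValueError("need at least 10 genera")
        if not 1 <= len(self.mucosal_taxa) < self.g_taxa:
            raise ValueError("need 1 <= |mucosal_taxa| < g_taxa")
        if len(self.studies) != len(self.n_animals_per_arm):
            raise ValueError("one arm size per study is required")
        if any(n < 1 for n in self.n_animals_per_arm):
            raise ValueError("every study arm must contain at least one animal")
        if len(set(self.studies)) != len(self.studies):
            raise ValueError("duplicate study labels")

    @property
    def dominant_taxon(self) -> str:
        return self.mucosal_taxa[0]

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        named = list(self.mucosal_taxa) + [
            t for t in DEFAULT_LUMINAL_TAXA if t not in self.mucosal_taxa
        ]
        fillers = [f"Genus_{i:03d}" for i in range(1, self.g_taxa + 1)]
        out = (named + fillers)[: self.g_taxa]
        if len(out) < self.g_taxa:
            raise ValueError("could not construct enough taxon labels")
        return tuple(out)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a simulated cohort."""

    design: CohortDesign
    mixing: pd.Series  # animal_id -> true m_i
    luminal_profiles: dict  # study -> CommunityProfile
    adhered_profiles: dict  # (study, treatment) -> mean CommunityProfile
    eating_propensity: pd.Series  # animal_id -> propensity (EF only)
    seed: int

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        df = self.mixing.rename("m_i").rename_axis("animal_id").reset_index()
        df.to_csv(d / "truth_mucosity.tsv", sep="\t", index=False, float_format="%.10g")
        params = asdict(self.design)
        params["mixing_seed"] = self.seed
        with open(d / "design.json", "w") as fh:
            json.dump(params, fh, indent=2, default=list)


# mass budget of the two base communities: the luminal community carries a
# small but nonzero mucosal block (the dominant adhered genus is virtually
# absent from colon content), while the adhered community concentrates a
# third of its mass on the dominant genus over a luminal-like background
_LUMINAL_MUCOSAL_MASS = 0.01
_LUMINAL_DOMINANT = 0.002
_ADHERED_DOMINANT = 0.35
_ADHERED_OTHER_MUCOSAL = 0.30
_RANK_DECAY = 0.78


def make_profiles(design: CohortDesign) -> tuple[CommunityProfile, CommunityProfile]:
    """Base luminal and mucosa-adhered community profiles for a design.

    Deterministic given ``design.seed``. The dominant adhered genus is at
    least 10x more abundant in the adhered than in the luminal profile by
    construction; the remaining mucosal genera are low-abundance but
    swab-enriched; non-mucosal mass follows a rank-decayed lognormal
    profile shared (up to budget) between the two communities.
    """
    taxa = design.taxon_ids
    mucosal = set(design.mucosal_taxa)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    g = len(taxa)
    is_mucosal = np.array([t in mucosal for t in taxa])
    is_dominant = np.array([t == design.dominant_taxon for t in taxa])

    # shared non-mucosal backbone: rank-decayed with lognormal jitter
    n_lum = int((~is_mucosal).sum())
    backbone = _RANK_DECAY ** np.arange(n_lum) * rng.lognormal(0.0, 0.5, size=n_lum)
    backbone /= backbone.sum()

    n_other = len(mucosal) - 1
    other_w = rng.lognormal(0.0, 0.4, size=n_other) if n_other else np.array([])
    if n_other:
        other_w /= other_w.sum()

    luminal = np.zeros(g)
    adhered = np.zeros(g)
    luminal[~is_mucosal] = (1.0 - _LUMINAL_MUCOSAL_MASS) * backbone
    adhered[~is_mucosal] = (1.0 - _ADHERED_DOMINANT - _ADHERED_OTHER_MUCOSAL) * backbone
    luminal[is_dominant] = _LUMINAL_DOMINANT
    adhered[is_dominant] = _ADHERED_DOMINANT
    other_idx = np.flatnonzero(is_mucosal & ~is_dominant)
    if n_other:
        luminal[other_idx] = (_LUMINAL_MUCOSAL_MASS - _LUMINAL_DOMINANT) * other_w
        adhered[other_idx] = _ADHERED_OTHER_MUCOSAL * other_w
    luminal /= luminal.sum()
    adhered /= adhered.sum()
    return CommunityProfile(taxa, luminal), CommunityProfile(taxa, adhered)


def _renormalise(p: np.ndarray) -> np.ndarray:
    return p / p.sum()


def simulate_cohort(
    design: CohortDesign,
) -> tuple[AbundanceTable, SampleMetadata, SyntheticTruth]:
    """Simulate paired swab/colon genus counts for every animal in a design.

    Per study, both base profiles receive the same per-taxon lognormal batch
    perturbation. Per animal ``a`` with mixing coefficient ``m_a``:

    * colon counts  ~ Multinomial(depth, Dirichlet(c * luminal_study))
    * swab counts   ~ Multinomial(depth, Dirichlet(c * mix_a)), with
      ``mix_a = m_a * adhered_arm + (1 - m_a) * luminal_study``

    where ``c`` is the overdispersion (Dirichlet concentration) scale. In EF
    animals the dominant adhered genus is multiplied by a per-animal
    suppression factor with mean ``ef_suppression`` before renormalising;
    the factor is modulated by the animal's eating propensity so that more
    eager eaters suppress the genus more (at ``ef_suppression = 1`` the
    modulation vanishes and the arms are exchangeable).
    """
    luminal0, adhered0 = make_profiles(design)
    taxa = design.taxon_ids
    g = len(taxa)
    dom = taxa.index(design.dominant_taxon)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 202]))

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    mixing: dict[str, float] = {}
    eating: dict[str, float] = {}
    luminal_profiles: dict[str, CommunityProfile] = {}
    adhered_profiles: dict[tuple[str, str], CommunityProfile] = {}
    low, high = design.mucosity_range

    for study, n_arm in zip(design.studies, design.n_animals_per_arm):
        batch = np.exp(rng.normal(0.0, design.batch_sigma, size=g))
        lum_s = _renormalise(luminal0.proportions * batch)
        adh_s = _renormalise(adhered0.proportions * batch)
        luminal_profiles[study] = CommunityProfile(taxa, lum_s)
        for treatment in ("CON", "EF"):
            adh_arm = adh_s.copy()
            if treatment == "EF":
                adh_arm[dom] *= design.ef_suppression
                adh_arm = _renormalise(adh_arm)
            adhered_profiles[(study, treatment)] = CommunityProfile(taxa, adh_arm)
            for i in range(n_arm):
                animal = f"{study}_{treatment}{i + 1:02d}"
                m = float(rng.uniform(low, high))
                score = np.nan
                adh_animal = adh_arm
                if treatment == "EF":
                    # eating propensity modulates suppression around its mean
                    e = float(rng.uniform(0.6, 1.4))
                    score = round(30.0 * e, 2)  # minutes/day of feed foraging
                    eating[animal] = e
                    if design.ef_suppression < 1:
                        factor = max(0.0, 1.0 - (1.0 - design.ef_suppression) * e)
                        adh_animal = adh_s.copy()
                        adh_animal[dom] = adh_s[dom] * factor
                        adh_animal = _renormalise(adh_animal)
                    m = min(1.0, max(0.0, m + design.ef_mucosity_shift))
                mixing[animal] = m
                mix = m * adh_animal + (1.0 - m) * lum_s
                litter = f"{study}_{treatment}_L{1 + i % 6}"
                for stype, profile in (("swab", mix), ("colon", lum_s)):
                    p = rng.dirichlet(design.overdispersion * profile)
                    counts = rng.multinomial(design.depth, p)
                    sid = f"{animal}_{'S' if stype == 'swab' else 'C'}"
                    rows.append(counts)
                    sample_ids.append(sid)
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "animal_id": animal,
                            "sample_type": stype,
                            "treatment": treatment,
                            "study": study,
                            "eating_score": score if stype == "swab" else score,
                            "litter": litter,
                        }
                    )

    table = AbundanceTable(tuple(sample_ids), taxa, np.vstack(rows))
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = SyntheticTruth(
        design=design,
        mixing=pd.Series(mixing, name="m_i"),
        luminal_profiles=luminal_profiles,
        adhered_profiles=adhered_profiles,
        eating_propensity=pd.Series(eating, name="eating_propensity", dtype=float),
        seed=design.seed,
    )
    return table, meta, truth


def write_cohort(
    table: AbundanceTable, meta: SampleMetadata, truth: SyntheticTruth, directory
) -> None:
    """Write a simulated cohort (counts, metadata, truth) as TSV/JSON files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_abundance(table, d / "abundance.tsv")
    write_metadata(meta, d / "metadata.tsv")
    truth.write(d)
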