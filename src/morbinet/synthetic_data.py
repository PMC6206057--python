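"""Synthetic multimorbidity cohorts with planted network structure.

Real stratified diagnosis summaries of the kind this pipeline consumes
(primary-care cohorts aggregated per 5-year age band and gender) are not
freely distributable, so the generator simulates *individual-level*
diagnosis matrices and reduces them to the exact summary format the
pipeline reads.  Simulating individuals — rather than sampling Jaccard
indices directly — guarantees that N, the prevalence counts and the
pairwise Jaccard indices are mutually consistent, which the exact 2x2
reconstruction of the relative-risk engine requires.

Generative model, per individual in a stratum:

* every disease ``i`` has a baseline probability ``p_i`` drawn once per
  cohort from ``baseline_prevalence_range`` (log-uniform) and held fixed
  across strata;
* each planted community draws an independent latent activation
  (probability ``community_activation``); while active it multiplies the
  probability of its member diseases by ``phi``;
* a hub disease is multiplied by its coupling strength whenever any of its
  target communities is active, which wires it across communities;
* a burst seed owns a latent burst factor that exists only at/after its
  onset age band; while active it boosts the seed and its >= 10 partner
  diseases, producing a sudden jump in strong comorbid edges;
* diagnoses are drawn independently given the latent state; afterwards,
  for each planted exclusion pair, an individual carrying both loses one
  of the two (chosen uniformly) with probability equal to the exclusivity
  strength;
* individuals with fewer than two diagnoses are dropped, matching the
  inclusion rule of multimorbidity studies (this shifts marginal
  prevalences slightly upward; see docs/methods.md).

Configurations whose boosts could push a probability above 1 are rejected
up front rather than silently clipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .association import CooccurrenceSummary

__all__ = [
    "PlantedCommunity",
    "PlantedHub",
    "PlantedExclusion",
    "PlantedBurst",
    "GeneratorConfig",
    "DiagnosisMatrix",
    "TruthLabels",
    "default_config",
    "null_config",
    "generate_cohort",
    "summarize",
    "disease_code",
    "make_catalog",
    "write_cohort",
    "AGE_BANDS",
    "GENDERS",
    "age_midpoint",
]

AGE_BANDS = (
    "19-24", "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85-89", "90+",
)
GENDERS = ("men", "women")

#: number of higher-level clinical chapters used for the coherence test
N_CHAPTERS = 21


def age_midpoint(band: str) -> float:
    """Midpoint age of a 5-year band; 92.5 for the open-ended 90+ band."""
    if band.endswith("+"):
        return float(band[:-1]) + 2.5
    lo, hi = band.split("-")
    return (float(lo) + float(hi) + 1.0) / 2.0


@dataclass
class PlantedCommunity:
    diseases: frozenset[int]
    phi: float  # within-group co-occurrence boost, > 1


@dataclass
class PlantedHub:
    disease: int
    targets: tuple[int, ...]  # indices into planted_communities
    coupling: float


@dataclass
class PlantedExclusion:
    pair: tuple[int, int]
    strength: float  # exclusivity in [0, 1]


@dataclass
class PlantedBurst:
    disease: int
    onset: int               # age-band index (within a gender sequence)
    coupling: float          # boost of the seed while the burst factor is active
    partners: tuple[int, ...]  # >= 10 partner diseases
    partner_coupling: float = 4.0
    # optional pre-onset anchor: couples the seed to one community in every
    # stratum so it is present in the networks before its burst begins
    anchor_community: int | None = None
    anchor_coupling: float = 1.0


@dataclass
class GeneratorConfig:
    """Full description of one synthetic cohort."""

    seed: int
    strata: tuple[tuple[str, str], ...]
    n_individuals_per_stratum: int
    n_diseases: int
    baseline_prevalence_range: tuple[float, float]
    planted_communities: tuple[PlantedCommunity, ...] = ()
    planted_hubs: tuple[PlantedHub, ...] = ()
    planted_exclusions: tuple[PlantedExclusion, ...] = ()
    planted_bursts: tuple[PlantedBurst, ...] = ()
    community_activation: float = 0.10
    burst_activation: float = 0.10

    def validate(self) -> None:
        d = self.n_diseases
        lo, hi = self.baseline_prevalence_range
        if not (0 < lo <= hi < 1):
            raise ValueError("baseline_prevalence_range must satisfy 0 < lo <= hi < 1")
        if self.n_individuals_per_stratum < 1 or d < 2:
            raise ValueError("need at least one individual and two diseases")
        for com in self.planted_communities:
            if com.phi <= 1:
                raise ValueError("community boost phi must exceed 1")
            if any(i >= d for i in com.diseases):
                raise ValueError("community disease index out of range")
        for hub in self.planted_hubs:
            if hub.disease >= d:
                raise ValueError("hub disease index out of range")
            if any(t >= len(self.planted_communities) for t in hub.targets):
                raise ValueError("hub target community out of range")
        for ex in self.planted_exclusions:
            if not 0 <= ex.strength <= 1:
                raise ValueError("exclusivity strength must lie in [0, 1]")
            if any(i >= d for i in ex.pair):
                raise ValueError("exclusion disease index out of range")
        for b in self.planted_bursts:
            if b.disease >= d or any(p >= d for p in b.partners):
                raise ValueError("burst disease index out of range")
            if len(b.partners) < 10:
                raise ValueError(
                    "a planted burst needs >= 10 partners so a degree leap of "
                    ">= 10 is achievable"
                )
            n_bands = len({s[0] for s in self.strata})
            if not 0 <= b.onset < n_bands:
                raise ValueError("burst onset stratum index out of range")
        # reject configurations whose combined boosts can exceed probability 1
        boost = np.ones(d)
        for com in self.planted_communities:
            for i in com.diseases:
                boost[i] *= com.phi
        for hub in self.planted_hubs:
            boost[hub.disease] *= hub.coupling
        for b in self.planted_bursts:
            boost[b.disease] *= b.coupling * b.anchor_coupling
            if b.anchor_community is not None and (
                b.anchor_community >= len(self.planted_communities)
            ):
                raise ValueError("burst anchor community out of range")
            for p in b.partners:
                boost[p] *= b.partner_coupling
        if float(np.max(boost) * hi) > 1.0:
            worst = int(np.argmax(boost))
            raise ValueError(
                f"infeasible configuration: disease index {worst} can reach "
                f"probability {boost[worst] * hi:.3f} > 1; lower its boosts or "
                "the baseline range"
            )


@dataclass
class DiagnosisMatrix:
    """Binary individuals x diseases incidence for one stratum."""

    stratum: tuple[str, str]
    matrix: np.ndarray  # bool, shape (n_individuals_kept, n_diseases)
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.dtype != bool:
            self.matrix = self.matrix.astype(bool)


@dataclass
class TruthLabels:
    """Exported ground truth of the planted structure."""

    hub_diseases: frozenset[str]
    community_memberships: dict[tuple[str, str], dict[str, int]]
    burst_seeds: dict[str, int]          # code -> onset age-band index
    burst_partners: dict[str, frozenset[str]]
    exclusion_pairs: frozenset[tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hub_diseases": sorted(self.hub_diseases),
            "community_memberships": {
                f"{band}:{gender}": members
                for (band, gender), members in self.community_memberships.items()
            },
            "burst_seeds": self.burst_seeds,
            "burst_partners": {k: sorted(v) for k, v in self.burst_partners.items()},
            "exclusion_pairs": [list(p) for p in sorted(self.exclusion_pairs)],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLabels":
        payload = json.loads(Path(path).read_text())
        memberships = {}
        for key, members in payload["community_memberships"].items():
            band, gender = key.split(":")
            memberships[(band, gender)] = {k: int(v) for k, v in members.items()}
        return cls(
            hub_diseases=frozenset(payload["hub_diseases"]),
            community_memberships=memberships,
            burst_seeds={k: int(v) for k, v in payload["burst_seeds"].items()},
            burst_partners={
                k: frozenset(v) for k, v in payload["burst_partners"].items()
            },
            exclusion_pairs=frozenset(
                tuple(p) for p in payload["exclusion_pairs"]
            ),
        )


def disease_code(i: int) -> str:
    """ICD-10-block-like code for disease index ``i`` (letter + two digits)."""
    return f"{chr(ord('A') + i // 20)}{i % 20:02d}"


def ordered_strata() -> tuple[tuple[str, str], ...]:
    return tuple((band, gender) for gender in GENDERS for band in AGE_BANDS)


def default_config(seed: int = 0) -> GeneratorConfig:
    """The package's reference cohort: 30 strata, 179 diseases, 20k each.

    Almost every disease belongs to one of 29 comorbidity communities of
    six diseases (multimorbidity background is pervasive, so each disease
    carries a stable floor of ~5 strong comorbid edges); the planted
    classes add distinguishable signatures on top of that floor:

    * 29 communities (6 diseases each, indices ``6c .. 6c+5``, 0-173),
      phi = 6, activation 0.10 -> within-community RR ~ 2.0;
    * 10 hubs: the first member of communities 0-9, each additionally
      coupled (strength 4) to one distinct target community (10-19),
      giving ~6 extra cross-community strong edges and roughly twice the
      weighted degree of a plain member — clearly central, but with a
      strong-edge degree that stays well below the burst leap threshold;
    * 5 burst seeds (174-178, outside the communities): each is anchored
      (strength 4) to one of communities 20-24 so it carries ~5 strong
      edges in every stratum; at/after age-band index 12 (80-84 years) a
      latent burst factor (activation 0.15) boosts the seed (x10) and its
      18 partners (x2.7; one partner per community 0-17), so the seed gains
      ~15 strong edges at once (seed-partner RR ~ 1.7) while
      partner-partner co-occurrence stays below the edge threshold;
    * 4 exclusion pairs among members of communities 21-28, strength 0.6
      (RR ~ 0.4, mutual exclusivity).

    Baselines are log-uniform in (0.02, 0.025), so every combined boost
    keeps probabilities below 1 and every disease passes the 1%
    prevalence filter in every stratum.
    """
    communities = tuple(
        PlantedCommunity(frozenset(range(6 * c, 6 * c + 6)), phi=6.0)
        for c in range(29)
    )
    hubs = tuple(
        PlantedHub(6 * c, (10 + c,), coupling=4.0) for c in range(10)
    )
    bursts = tuple(
        PlantedBurst(
            disease=174 + k,
            onset=12,
            coupling=10.0,
            partners=tuple(6 * c + 1 + k for c in range(18)),
            partner_coupling=2.7,
            anchor_community=20 + k,
            anchor_coupling=4.0,
        )
        for k in range(5)
    )
    exclusions = tuple(
        PlantedExclusion((6 * (21 + 2 * k) + 4, 6 * (22 + 2 * k) + 4),
                         strength=0.6)
        for k in range(4)
    )
    return GeneratorConfig(
        seed=seed,
        strata=ordered_strata(),
        n_individuals_per_stratum=20_000,
        n_diseases=179,
        baseline_prevalence_range=(0.02, 0.025),
        planted_communities=communities,
        planted_hubs=hubs,
        planted_exclusions=exclusions,
        planted_bursts=bursts,
        burst_activation=0.15,
    )


def null_config(
    seed: int = 0,
    n_strata_per_gender: int = 10,
    n_individuals: int = 3000,
    n_diseases: int = 60,
    baseline: float = 0.05,
) -> GeneratorConfig:
    """A structure-free cohort with identical baselines for every disease.

    Used for null calibration: with i.i.d. diseases the label-permutation
    nulls are exactly exchangeable, so permutation p-values are uniform on
    their achievable grid.
    """
    strata = tuple(
        (band, gender)
        for gender in GENDERS
        for band in AGE_BANDS[:n_strata_per_gender]
    )
    return GeneratorConfig(
        seed=seed,
        strata=strata,
        n_individuals_per_stratum=n_individuals,
        n_diseases=n_diseases,
        baseline_prevalence_range=(baseline, baseline),
    )


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[DiagnosisMatrix], TruthLabels]:
    """Simulate one cohort and its ground-truth labels.

    Returns one :class:`DiagnosisMatrix` per stratum (in ``config.strata``
    order) plus :class:`TruthLabels`.  Deterministic given ``config.seed``.
    """
    config.validate()
    d = config.n_diseases
    codes = tuple(disease_code(i) for i in range(d))
    root = np.random.SeedSequence(config.seed)
    base_ss, *stratum_ss = root.spawn(1 + len(config.strata))
    base_rng = np.random.default_rng(base_ss)
    lo, hi = config.baseline_prevalence_range
    baselines = np.exp(base_rng.uniform(np.log(lo), np.log(hi), size=d))

    bands_order = {band: k for k, band in enumerate(dict.fromkeys(
        s[0] for s in config.strata))}

    matrices: list[DiagnosisMatrix] = []
    for (band, gender), ss in zip(config.strata, stratum_ss):
        rng = np.random.default_rng(ss)
        n = config.n_individuals_per_stratum
        age_idx = bands_order[band]

        prob = np.tile(baselines, (n, 1))
        com_active = np.zeros((len(config.planted_communities), n), dtype=bool)
        for ci, com in enumerate(config.planted_communities):
            com_active[ci] = rng.random(n) < config.community_activation
            members = sorted(com.diseases)
            prob[np.ix_(com_active[ci], members)] *= com.phi
        for hub in config.planted_hubs:
            any_active = np.zeros(n, dtype=bool)
            for t in hub.targets:
                any_active |= com_active[t]
            prob[any_active, hub.disease] *= hub.coupling
        for b in config.planted_bursts:
            if b.anchor_community is not None:
                prob[com_active[b.anchor_community], b.disease] *= b.anchor_coupling
            if age_idx >= b.onset:
                active = rng.random(n) < config.burst_activation
                prob[active, b.disease] *= b.coupling
                prob[np.ix_(active, list(b.partners))] *= b.partner_coupling

        x = rng.random((n, d)) < prob
        for ex in config.planted_exclusions:
            i, j = ex.pair
            both = x[:, i] & x[:, j]
            if both.any():
                hit = both & (rng.random(n) < ex.strength)
                drop_i = rng.random(n) < 0.5
                x[hit & drop_i, i] = False
                x[hit & ~drop_i, j] = False

        keep = x.sum(axis=1) >= 2  # multimorbidity inclusion rule
        matrices.append(DiagnosisMatrix((band, gender), x[keep], codes))

    memberships: dict[str, int] = {}
    for cid, com in enumerate(config.planted_communities):
        for i in com.diseases:
            memberships[codes[i]] = cid
    truth = TruthLabels(
        hub_diseases=frozenset(codes[h.disease] for h in config.planted_hubs),
        community_memberships={s: dict(memberships) for s in config.strata},
        burst_seeds={codes[b.disease]: b.onset for b in config.planted_bursts},
        burst_partners={
            codes[b.disease]: frozenset(codes[p] for p in b.partners)
            for b in config.planted_bursts
        },
        exclusion_pairs=frozenset(
            tuple(sorted((codes[ex.pair[0]], codes[ex.pair[1]])))
            for ex in config.planted_exclusions
        ),
    )
    return matrices, truth


def summarize(matrix: DiagnosisMatrix) -> CooccurrenceSummary:
    """Reduce a diagnosis matrix to its co-occurrence summary.

    ``N`` is the number of retained individuals, ``N_i`` the column sums
    and ``J_ij = C_ij / (N_i + N_j - C_ij)``.  Pairs where both diseases
    have zero prevalence are omitted (the Jaccard index is undefined);
    zero-prevalence diseases are kept in the prevalence map but flagged.
    """
    x = matrix.matrix
    if x.size == 0:
        raise ValueError("empty diagnosis matrix")
    codes = matrix.codes
    if len(set(codes)) != len(codes):
        raise ValueError("duplicated disease codes")
    counts = x.sum(axis=0).astype(np.int64)
    zero = [codes[i] for i in np.flatnonzero(counts == 0)]
    if zero:
        warnings.warn(
            f"diseases with zero prevalence in stratum {matrix.stratum}: {zero}",
            stacklevel=2,
        )
    xf = x.astype(np.float32)
    c = (xf.T @ xf).astype(np.int64)
    jaccard: dict[tuple[str, str], float] = {}
    d = len(codes)
    union = counts[:, None] + counts[None, :] - c
    iu, ju = np.triu_indices(d, k=1)
    denom = union[iu, ju]
    ok = denom > 0
    jvals = np.zeros(len(iu))
    jvals[ok] = c[iu, ju][ok] / denom[ok]
    for k in np.flatnonzero(ok):
        jaccard[(codes[iu[k]], codes[ju[k]])] = float(jvals[k])
    return CooccurrenceSummary(
        stratum=matrix.stratum,
        n=int(x.shape[0]),
        prevalence={codes[i]: int(counts[i]) for i in range(d)},
        jaccard=jaccard,
    )


def make_catalog(config: GeneratorConfig) -> dict[str, dict]:
    """Disease catalog: code -> {chapter, chronic}.

    Chapters mirror higher-level clinical classification: each planted
    community gets its own chapter (so chapter labels align with network
    topology, as in real morbidity networks), every other disease cycles
    through the remaining chapters.  Chronic flags: community members and
    burst seeds are chronic; other diseases alternate deterministically.
    """
    d = config.n_diseases
    chapter_names = [f"CH{k + 1:02d}" for k in range(N_CHAPTERS)]
    chapter: dict[int, str] = {}
    for cid, com in enumerate(config.planted_communities):
        for i in com.diseases:
            chapter[i] = chapter_names[cid % N_CHAPTERS]
    n_com = max(1, len(config.planted_communities))
    rest = [i for i in range(d) if i not in chapter]
    for k, i in enumerate(rest):
        chapter[i] = chapter_names[(n_com + k) % N_CHAPTERS]
    chronic = {i: (i % 3 != 2) for i in range(d)}
    for com in config.planted_communities:
        for i in com.diseases:
            chronic[i] = True
    for b in config.planted_bursts:
        chronic[b.disease] = True
    return {
        disease_code(i): {"chapter": chapter[i], "chronic": bool(chronic[i])}
        for i in range(d)
    }


def write_cohort(
    out_dir: str | Path,
    summaries: list[CooccurrenceSummary],
    catalog: dict[str, dict],
    truth: TruthLabels | None = None,
) -> None:
    """Write the pipeline input bundle as plain TSV/JSON files.

    ``prevalence.tsv``: stratum, disease_code, count, population;
    ``pairs.tsv``: stratum, code_i, code_j, jaccard;
    ``catalog.tsv``: code, chapter, chronic_flag; ``truth.json`` optional.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "prevalence.tsv", "w") as fh:
        fh.write("stratum\tdisease_code\tcount\tpopulation\n")
        for s in summaries:
            label = f"{s.stratum[0]}:{s.stratum[1]}"
            for code in sorted(s.prevalence):
                fh.write(f"{label}\t{code}\t{s.prevalence[code]}\t{s.n}\n")
    with open(out / "pairs.tsv", "w") as fh:
        fh.write("stratum\tcode_i\tcode_j\tjaccard\n")
        for s in summaries:
            label = f"{s.stratum[0]}:{s.stratum[1]}"
            for (a, b) in sorted(s.jaccard):
                fh.write(f"{label}\t{a}\t{b}\t{s.jaccard[(a, b)]!r}\n")
    with open(out / "catalog.tsv", "w") as fh:
        fh.write("code\tchapter\tchronic_flag\n")
        for code in sorted(catalog):
            row = catalog[code]
            fh.write(f"{code}\t{row['chapter']}\t{int(row['chronic'])}\n")
    if truth is not None:
        truth.to_json(out / "truth.json")
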