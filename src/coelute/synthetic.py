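"""Ground-truthed synthetic CF-MS data.

Emulates multi-species co-fractionation experiments at desk scale: planted
protein complexes co-elute as Gaussian peaks in fraction space, member
profiles are scaled by log-normal abundances and sampled as Poisson counts,
orthogroups drop out of individual experiments, and each orthogroup is
present in a random subset of species.  Matched external-assay evidence and
toy ontologies are generated from the same truth so every downstream stage
of the pipeline can be tested offline against known answers.

There is no retention-time physics here and no peptide-level structure:
profiles are generated directly at the orthogroup level.  All stochastic
choices draw from named substreams of a single seed (see ``coelute._rng``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .elution import ElutionMatrix
from .errors import ParameterError
from .pairs import PairKey, all_pairs, cocomplex_pairs, pair_key
from .validation import ExternalEvidence

__all__ = [
    "SimulationParams",
    "TruthComplexSet",
    "generate_truth",
    "simulate_experiment",
    "simulate_all_experiments",
    "simulate_external_assay",
    "simulate_annotations",
    "write_complexes_tsv",
    "write_evidence_tsv",
    "write_annotations_tsv",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study-design and noise parameters for the simulator.

    Defaults describe a small multi-species brain CF-MS study: 3 species
    with 2 fractionation experiments each (40 fractions per experiment),
    35 planted complexes of 2-8 members plus 25 monomeric orthogroups.
    Abundance is the expected peak-height PSM count per fraction,
    log-normal across orthogroups (median 50).  ``peak_sd`` is the elution
    peak width and ``coelution_jitter_sd`` the per-member offset of its
    peak center from the complex's center, both in fraction units.
    """

    n_species: int = 3
    experiments_per_species: int = 2
    fractions_per_experiment: int = 40
    n_complexes: int = 35
    n_monomers: int = 25
    min_complex_size: int = 2
    max_complex_size: int = 8
    abundance_mu: float = float(np.log(50.0))
    abundance_sigma: float = 0.75
    peak_sd: float = 2.0
    coelution_jitter_sd: float = 0.6
    dropout_prob: float = 0.10
    species_retention: float = 0.90
    seed: int = 0

    def __post_init__(self):
        for name in ("n_species", "experiments_per_species",
                     "fractions_per_experiment", "n_complexes"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.n_monomers < 0:
            raise ParameterError("n_monomers must be >= 0")
        if self.max_complex_size < 2 or self.min_complex_size < 2:
            raise ParameterError("complex sizes must allow >= 2 members")
        if self.min_complex_size > self.max_complex_size:
            raise ParameterError("min_complex_size > max_complex_size")
        for name in ("dropout_prob", "species_retention"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.peak_sd <= 0:
            raise ParameterError("peak_sd must be > 0")
        if self.coelution_jitter_sd < 0:
            raise ParameterError("coelution_jitter_sd must be >= 0")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


@dataclass(frozen=True)
class TruthComplexSet:
    """Planted ground truth: complexes, monomers, species presence and
    per-orthogroup expected peak heights."""

    complexes: list[frozenset[str]]
    monomers: frozenset[str]
    species_presence: dict[str, frozenset[str]]
    abundances: dict[str, float]

    @property
    def orthogroups(self) -> list[str]:
        return sorted(self.species_presence)

    def cocomplex_pairs(self) -> set[PairKey]:
        return cocomplex_pairs(self.complexes)

    def complex_of(self) -> dict[str, list[int]]:
        """Orthogroup -> indices of the complexes containing it."""
        out: dict[str, list[int]] = {}
        for k, cpx in enumerate(self.complexes):
            for og in cpx:
                out.setdefault(og, []).append(k)
        return out


def generate_truth(params: SimulationParams) -> TruthComplexSet:
    """Draw the planted complex map, species presence and abundances.

    Complex sizes are uniform on [min, max]; members are drawn without
    replacement from the complex-member pool, so complexes are disjoint
    (overlap can be introduced downstream by ontology terms, which union
    complexes).  Every orthogroup retains each species with probability
    ``species_retention`` and is forced into at least one species.
    """
    rng = substream(params.seed, "truth")
    sizes = rng.integers(params.min_complex_size, params.max_complex_size + 1,
                         size=params.n_complexes)
    n_members = int(sizes.sum())
    n_total = n_members + params.n_monomers
    width = len(str(n_total))
    ids = [f"OG{str(i).zfill(width)}" for i in range(n_total)]
    order = rng.permutation(n_total)
    it = iter(order)
    complexes = [
        frozenset(ids[next(it)] for _ in range(s)) for s in sizes
    ]
    monomers = frozenset(ids[next(it)] for _ in range(params.n_monomers))

    presence: dict[str, frozenset[str]] = {}
    species = params.species
    for og in ids:
        mask = rng.random(params.n_species) < params.species_retention
        if not mask.any():
            mask[rng.integers(params.n_species)] = True
        presence[og] = frozenset(s for s, m in zip(species, mask) if m)

    abund = np.exp(rng.normal(params.abundance_mu, params.abundance_sigma,
                              size=n_total))
    return TruthComplexSet(complexes, monomers, presence,
                           dict(zip(ids, abund.tolist())))


def simulate_experiment(
    truth: TruthComplexSet,
    species: str,
    params: SimulationParams,
    experiment_id: str | None = None,
    expectation_mode: bool = False,
) -> ElutionMatrix:
    """Simulate one fractionation experiment for one species.

    Each complex draws a peak-center fraction; each member's profile is a
    Gaussian peak at center + jitter, height = its abundance, and counts are
    Poisson-sampled (skipped in ``expectation_mode``, which also disables
    jitter and dropout to produce exactly co-linear member profiles).
    Orthogroups absent from the species are excluded; dropped-out
    orthogroups keep an all-zero row.
    """
    if species not in set().union(*truth.species_presence.values()):
        raise ParameterError(f"unknown species {species!r}")
    experiment_id = experiment_id or f"{species}_exp"
    rng = substream(params.seed, "experiment", experiment_id)

    ogs = [og for og in truth.orthogroups if species in truth.species_presence[og]]
    F = params.fractions_per_experiment
    frac = np.arange(F, dtype=float)

    # all draws happen in a fixed order regardless of mode, so expectation
    # mode shares peak centers with the corresponding stochastic run
    centers = rng.uniform(0, F - 1, size=len(truth.complexes))
    jitter = rng.normal(0.0, params.coelution_jitter_sd, size=len(ogs))
    monomer_centers = rng.uniform(0, F - 1, size=len(ogs))
    dropout = rng.random(len(ogs))
    membership = truth.complex_of()

    profiles = np.zeros((len(ogs), F))
    for i, og in enumerate(ogs):
        in_complexes = membership.get(og, [])
        if in_complexes:
            # overlapping membership: peak at the first complex's center
            c = centers[in_complexes[0]]
            if not expectation_mode:
                c = c + jitter[i]
        else:
            c = monomer_centers[i]
        lam = truth.abundances[og] * np.exp(-((frac - c) ** 2)
                                            / (2 * params.peak_sd ** 2))
        if expectation_mode:
            profiles[i] = lam
        else:
            if dropout[i] < params.dropout_prob:
                continue  # dropout: all-zero row
            profiles[i] = rng.poisson(lam)

    dtype = float if expectation_mode else np.int64
    data = pd.DataFrame(profiles.astype(dtype), index=ogs,
                        columns=[f"frac{i}" for i in range(F)])
    return ElutionMatrix(experiment_id, data)


def simulate_all_experiments(
    truth: TruthComplexSet, params: SimulationParams,
    expectation_mode: bool = False,
) -> dict[str, list[ElutionMatrix]]:
    """All experiments of the study design, grouped by species."""
    out: dict[str, list[ElutionMatrix]] = {}
    for sp in params.species:
        out[sp] = [
            simulate_experiment(truth, sp, params,
                                experiment_id=f"{sp}_e{r + 1}",
                                expectation_mode=expectation_mode)
            for r in range(params.experiments_per_species)
        ]
    return out


def simulate_external_assay(
    truth: TruthComplexSet,
    kind: str,
    sensitivity: float,
    fp_rate: float,
    seed: int,
    universe_fraction: float = 1.0,
) -> ExternalEvidence:
    """Emulate an independent interaction assay over the planted truth.

    The tested universe is a random ``universe_fraction`` subset of
    orthogroups (for ``bait_prey``, bait and prey sets are drawn
    independently at that fraction).  True co-complex pairs inside the
    universe are reported positive with probability ``sensitivity``; other
    tested pairs with probability ``fp_rate``.
    """
    if kind not in ("all_by_all", "bait_prey"):
        raise ParameterError(f"unknown assay kind {kind!r}")
    for name, p in (("sensitivity", sensitivity), ("fp_rate", fp_rate),
                    ("universe_fraction", universe_fraction)):
        if not 0 <= p <= 1:
            raise ParameterError(f"{name} must be in [0, 1]")
    rng = substream(seed, "assay", kind)
    ogs = np.array(truth.orthogroups)
    true_pairs = truth.cocomplex_pairs()

    def subset(frac):
        k = max(1, int(round(frac * len(ogs))))
        return set(rng.choice(ogs, size=k, replace=False).tolist())

    if kind == "all_by_all":
        universe = subset(universe_fraction)
        tested = all_pairs(universe)
        baits = preys = None
    else:
        baits, preys = subset(universe_fraction), subset(universe_fraction)
        tested = {pair_key(b, p) for b in baits for p in preys if b != p}
        universe = baits | preys

    positives = set()
    for p in sorted(tested):
        rate = sensitivity if p in true_pairs else fp_rate
        if rng.random() < rate:
            positives.add(p)
    return ExternalEvidence(
        kind=kind, positives=frozenset(positives),
        universe=frozenset(universe),
        baits=frozenset(baits) if baits else None,
        preys=frozenset(preys) if preys else None,
    )


def simulate_annotations(
    truth: TruthComplexSet, n_terms: int, seed: int,
    noise_members: int = 2,
) -> tuple[dict[str, set[str]], list[tuple[str, str]]]:
    """Toy ontology: a rooted DAG of terms annotated with orthogroup sets.

    The root term unions all complexes; each further term picks a parent
    among earlier terms and annotates a random subset of the parent's
    complexes plus a few noise monomers, so child sets are near-subsets of
    their parents the way real ontologies behave.  Returns the direct
    term -> orthogroup table and child -> parent edges.
    """
    if n_terms < 1:
        raise ParameterError("n_terms must be >= 1")
    rng = substream(seed, "annotations")
    monomers = sorted(truth.monomers)

    term_complexes: dict[str, list[int]] = {
        "T000": list(range(len(truth.complexes)))
    }
    terms = {"T000": set().union(*truth.complexes) if truth.complexes else set()}
    edges: list[tuple[str, str]] = []
    names = [f"T{str(i).zfill(3)}" for i in range(n_terms)]
    for i in range(1, n_terms):
        parent = names[rng.integers(i)]
        pool = term_complexes[parent]
        k = max(1, int(rng.integers(1, max(2, len(pool)))))
        chosen = sorted(rng.choice(pool, size=min(k, len(pool)),
                                   replace=False).tolist())
        members: set[str] = set()
        for c in chosen:
            members |= truth.complexes[c]
        if monomers and noise_members:
            n_noise = int(rng.integers(0, noise_members + 1))
            members |= set(rng.choice(monomers,
                                      size=min(n_noise, len(monomers)),
                                      replace=False).tolist())
        term_complexes[names[i]] = chosen
        terms[names[i]] = members
        edges.append((names[i], parent))
    return terms, edges


def correlation_network(params: SimulationParams, threshold: float = 0.5,
                        min_total_psms: float = 60):
    """Simulate a study and build a weighted co-elution network directly
    from Pearson correlations on the all-experiment concatenation.

    A lightweight stand-in for the full supervised pipeline when only a
    realistic weighted network topology is needed (e.g. null calibration
    of seed propagation).  Returns ``(truth, ScoredNetwork)`` with edge
    weight = Pearson r >= ``threshold``.
    """
    from .elution import concatenate_by_species, filter_min_abundance
    from .features import build_feature_table
    from .scoring import build_network

    truth = generate_truth(params)
    by_species = simulate_all_experiments(truth, params)
    flat = [m for mats in by_species.values() for m in mats]
    _, filtered = filter_min_abundance(flat, min_total_psms)
    concat = concatenate_by_species({"all": filtered})["all"]
    table = build_feature_table({"study": concat}, seed=params.seed)
    scores = table["study__pearson"].clip(lower=0.0, upper=1.0)
    return truth, build_network(scores, threshold)


# --- plain-text writers ----------------------------------------------------

def write_complexes_tsv(complexes, path: str | Path) -> None:
    """One complex per line, tab-separated member IDs (gold-standard style)."""
    with open(path, "w") as fh:
        for cpx in complexes:
            fh.write("\t".join(sorted(cpx)) + "\n")


def write_evidence_tsv(ev: ExternalEvidence, path: str | Path) -> None:
    """2-column positive-pair TSV; bait/prey lists as sidecar files."""
    path = Path(path)
    with open(path, "w") as fh:
        for a, b in sorted(ev.positives):
            fh.write(f"{a}\t{b}\n")
    if ev.kind == "bait_prey":
        for name, s in (("bait", ev.baits), ("prey", ev.preys)):
            with open(path.with_suffix(f".{name}.txt"), "w") as fh:
                fh.write("\n".join(sorted(s)) + "\n")


def write_annotations_tsv(terms: dict[str, set[str]],
                          edges: list[tuple[str, str]],
                          term_path: str | Path,
                          edge_path: str | Path) -> None:
    with open(term_path, "w") as fh:
        for t in sorted(terms):
            for og in sorted(terms[t]):
                fh.write(f"{t}\t{og}\n")
    with open(edge_path, "w") as fh:
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")
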