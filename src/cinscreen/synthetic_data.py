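"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators stand in for the real data sources so that every
downstream stage can be scored against a known ground truth:

* ``simulate_count_datasets`` — multi-study negative-binomial RNA-seq
  counts with a shared, direction-consistent planted treatment signature
  plus study-private differential genes, and an ortholog table for the
  mouse-labeled studies (with configurable unmapped and one-to-many
  fractions).
* ``simulate_faers_tables`` — versioned adverse-event cases in the
  ``$``-delimited DEMO/DRUG/REAC dialect.  The indexed reaction is drawn
  from a logistic model whose logit is shifted by ``log(odds_multiplier)``
  for each co-medication present, so a multiplier below 1 plants a
  protective signal and above 1 a risk signal.
* ``simulate_signature_library`` — a perturbagen x gene score matrix with
  planted reversers (query-up genes depressed, query-down genes elevated)
  and mimickers (the opposite) on a background of i.i.d. Gaussian noise.

All generators are pure functions of their spec (including the seed):
identical specs give byte-identical outputs and serializations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ReferenceSignatureLibrary
from .signature import CONTROL, TREATED, CountDataset, GeneSignature

__all__ = [
    "TranscriptomeSimSpec",
    "FaersSimSpec",
    "CoDrug",
    "LibrarySimSpec",
    "simulate_count_datasets",
    "simulate_faers_tables",
    "simulate_signature_library",
    "human_gene_universe",
]

#: score-unit shift applied to planted reverser/mimicker genes at strength 1
LIBRARY_SHIFT_SCALE = 3.0

INDEXED_REACTION = "ACUTE KIDNEY INJURY"
N_DISTRACTOR_REACTIONS = 3
DISTRACTOR_VOCABULARY = [f"REACTION {i:02d}" for i in range(1, 41)]


def human_gene_universe(n_genes: int) -> list[str]:
    """Synthetic human symbol universe G0001..G{n}."""
    return [f"G{i:04d}" for i in range(1, n_genes + 1)]


def _mouse_symbol(human: str) -> str:
    return human.lower()


def _validate(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ValueError(f"{fieldname}: {message}")


# ---------------------------------------------------------------------------
# transcriptome counts
# ---------------------------------------------------------------------------


@dataclass
class TranscriptomeSimSpec:
    """Multi-study NB count simulation with a planted shared signature.

    Defaults emulate three small two-group studies (two mouse, one human)
    with a shared signature of 152 up / 56 down genes at a 4-fold effect,
    mirroring the shape of the published nephrotoxicity signature.
    """

    n_genes: int = 2000
    n_studies: int = 3
    samples_per_group: int = 4
    planted_up: frozenset = frozenset()
    planted_down: frozenset = frozenset()
    log2_effect: float = 2.0
    study_specific_frac: float = 0.05
    dispersion: float = 0.1
    baseline_mean_log_range: tuple[float, float] = (math.log(50.0), math.log(2000.0))
    unmapped_frac: float = 0.05
    one_to_many_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_up = frozenset(self.planted_up)
        self.planted_down = frozenset(self.planted_down)
        _validate(self.n_genes >= 1, "n_genes", "must be >= 1")
        _validate(self.n_studies >= 1, "n_studies", "must be >= 1")
        _validate(self.samples_per_group >= 2, "samples_per_group", "must be >= 2")
        _validate(not (self.planted_up & self.planted_down), "planted_up", "overlaps planted_down")
        _validate(self.log2_effect >= 0, "log2_effect", "must be >= 0")
        _validate(0 <= self.study_specific_frac <= 1, "study_specific_frac", "must be in [0, 1]")
        _validate(self.dispersion > 0, "dispersion", "must be > 0")
        _validate(0 <= self.unmapped_frac <= 1, "unmapped_frac", "must be in [0, 1]")
        _validate(0 <= self.one_to_many_frac <= 1, "one_to_many_frac", "must be in [0, 1]")
        lo, hi = self.baseline_mean_log_range
        _validate(lo <= hi, "baseline_mean_log_range", "must be (low, high)")
        universe = set(human_gene_universe(self.n_genes))
        missing = (self.planted_up | self.planted_down) - universe
        _validate(not missing, "planted_up/planted_down", f"genes outside universe: {sorted(missing)[:5]}")

    @classmethod
    def with_planted(cls, n_up: int = 152, n_down: int = 56, seed: int = 0, **kwargs) -> "TranscriptomeSimSpec":
        """Spec whose planted sets are the first ``n_up`` + ``n_down`` symbols."""
        n_genes = kwargs.pop("n_genes", 2000)
        uni = human_gene_universe(n_genes)
        if n_up + n_down > n_genes:
            raise ValueError("planted sets exceed gene universe")
        return cls(
            n_genes=n_genes,
            planted_up=frozenset(uni[:n_up]),
            planted_down=frozenset(uni[n_up : n_up + n_down]),
            seed=seed,
            **kwargs,
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mu + dispersion * mu^2 (gamma-Poisson)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion)
    return rng.poisson(lam)


def simulate_count_datasets(
    spec: TranscriptomeSimSpec,
) -> tuple[list[CountDataset], list[tuple[str, str]], dict]:
    """Generate one CountDataset per study plus the ortholog table and truth.

    Returns ``(datasets, ortholog_table, truth)``.  Studies after the last
    are tagged mouse except the final one, which is human (with >=2 studies);
    mouse datasets use lower-case symbols resolvable through the table.
    The truth record lists the planted shared and study-private memberships.
    """
    rng = np.random.default_rng(spec.seed)
    universe = human_gene_universe(spec.n_genes)
    idx_of = {g: i for i, g in enumerate(universe)}
    up_idx = np.array(sorted(idx_of[g] for g in spec.planted_up), dtype=int)
    down_idx = np.array(sorted(idx_of[g] for g in spec.planted_down), dtype=int)
    planted = set(up_idx) | set(down_idx)
    free = np.array([i for i in range(spec.n_genes) if i not in planted], dtype=int)

    lo, hi = spec.baseline_mean_log_range
    effect = 2.0**spec.log2_effect
    datasets: list[CountDataset] = []
    private_truth: dict[str, dict[str, list[str]]] = {}
    n = spec.samples_per_group
    for s in range(spec.n_studies):
        is_human = s == spec.n_studies - 1 and spec.n_studies >= 2
        species = "human" if is_human else "mouse"
        name = f"study{s + 1}"
        mu0 = np.exp(rng.uniform(lo, hi, size=spec.n_genes))

        n_private = int(round(spec.study_specific_frac * spec.n_genes))
        n_private = min(n_private, free.size)
        priv = rng.choice(free, size=n_private, replace=False) if n_private else np.array([], dtype=int)
        priv_dir = rng.integers(0, 2, size=n_private) * 2 - 1  # -1 or +1

        fold = np.ones(spec.n_genes)
        fold[up_idx] = effect
        fold[down_idx] = 1.0 / effect
        fold[priv] = np.where(priv_dir > 0, effect, 1.0 / effect)

        mu = np.column_stack([np.tile(mu0, (n, 1)).T, np.tile(mu0 * fold, (n, 1)).T])
        counts = _nb_draw(rng, mu, spec.dispersion).astype(np.int64)

        genes = universe if is_human else [_mouse_symbol(g) for g in universe]
        samples = [f"{name}_c{j + 1}" for j in range(n)] + [f"{name}_t{j + 1}" for j in range(n)]
        group_of = {x: (CONTROL if j < n else TREATED) for j, x in enumerate(samples)}
        datasets.append(CountDataset(name, list(genes), samples, counts, group_of, species))
        private_truth[name] = {
            "up": sorted(universe[i] for i, d in zip(priv, priv_dir) if d > 0),
            "down": sorted(universe[i] for i, d in zip(priv, priv_dir) if d < 0),
        }

    # ortholog table: one row per mouse gene, minus unmapped, plus one-to-many
    n_unmapped = int(round(spec.unmapped_frac * spec.n_genes))
    n_multi = int(round(spec.one_to_many_frac * spec.n_genes))
    perm = rng.permutation(spec.n_genes)
    unmapped_set = set(perm[:n_unmapped].tolist())
    multi_set = set(perm[n_unmapped : n_unmapped + n_multi].tolist())
    ortholog_table: list[tuple[str, str]] = []
    for i, g in enumerate(universe):
        if i in unmapped_set:
            continue
        ortholog_table.append((_mouse_symbol(g), g))
        if i in multi_set:
            ortholog_table.append((_mouse_symbol(g), f"{g}A"))

    truth = {
        "planted_up": sorted(spec.planted_up),
        "planted_down": sorted(spec.planted_down),
        "study_private": private_truth,
        "unmapped_mouse_symbols": sorted(_mouse_symbol(universe[i]) for i in unmapped_set),
        "log2_effect": spec.log2_effect,
    }
    return datasets, ortholog_table, truth


# ---------------------------------------------------------------------------
# adverse-event reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoDrug:
    """A co-medication: odds_multiplier < 1 protective, > 1 risk, = 1 null."""

    name: str
    atc_code: str
    prevalence: float
    odds_multiplier: float


def _default_co_drugs() -> tuple[CoDrug, ...]:
    nulls = tuple(
        CoDrug(f"NULLDRUG {i:02d}", f"N{i:02d}AB{i:02d}", prev, 1.0)
        for i, prev in enumerate([0.05, 0.08, 0.10, 0.12, 0.15, 0.18, 0.20, 0.25], start=1)
    )
    return (
        CoDrug("PALONOSETRON", "A04AA05", 0.2, 0.3),
        CoDrug("GENTAMICIN", "J01GB03", 0.1, 3.0),
    ) + nulls


def _default_synonyms(co_drugs: Sequence[CoDrug]) -> dict[str, str]:
    table = {"CISPLATIN": "L01XA01", "CISPLATIN INJECTION": "L01XA01"}
    for d in co_drugs:
        table[d.name] = d.atc_code
        table[f"{d.name} HCL"] = d.atc_code
    return table


@dataclass
class FaersSimSpec:
    """Versioned adverse-event case simulation under a logistic event model."""

    n_cases: int = 200_000
    p_drug_a: float = 0.1
    co_drugs: tuple[CoDrug, ...] = field(default_factory=_default_co_drugs)
    baseline_event_prob: float = 0.3
    background_event_prob: float = 0.05
    duplicate_frac: float = 0.2
    synonym_table: Mapping[str, str] = field(default_factory=dict)
    drug_a_name: str = "CISPLATIN"
    drug_a_atc: str = "L01XA01"
    seed: int = 0

    def __post_init__(self) -> None:
        self.co_drugs = tuple(self.co_drugs)
        if not self.synonym_table:
            self.synonym_table = _default_synonyms(self.co_drugs)
        _validate(self.n_cases >= 1, "n_cases", "must be >= 1")
        for fieldname, p in [
            ("p_drug_a", self.p_drug_a),
            ("baseline_event_prob", self.baseline_event_prob),
            ("background_event_prob", self.background_event_prob),
        ]:
            _validate(0 < p < 1, fieldname, "must be in (0, 1)")
        _validate(0 <= self.duplicate_frac <= 1, "duplicate_frac", "must be in [0, 1]")
        resolved = {v for v in self.synonym_table.values()}
        for d in self.co_drugs:
            _validate(0 < d.prevalence < 1, "co_drugs", f"{d.name}: prevalence must be in (0, 1)")
            _validate(d.odds_multiplier > 0, "co_drugs", f"{d.name}: odds_multiplier must be > 0")
            _validate(d.atc_code in resolved, "synonym_table", f"cannot resolve co-drug {d.name!r}")
        _validate(self.drug_a_atc in resolved, "synonym_table", f"cannot resolve drug A {self.drug_a_name!r}")


def simulate_faers_tables(spec: FaersSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate DEMO/DRUG/REAC tables (as DataFrames) plus the truth record.

    ``duplicate_frac`` of the cases are emitted twice: an earlier version
    whose drug list is perturbed with probability 0.5, and the final
    version that carries the truth.  Verbatim drug strings are drawn from
    the synonym table's variants for each drug.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    has_a = rng.random(n) < spec.p_drug_a
    co_mat = np.column_stack([rng.random(n) < d.prevalence for d in spec.co_drugs]) if spec.co_drugs else np.zeros((n, 0), bool)

    base = np.where(has_a, spec.baseline_event_prob, spec.background_event_prob)
    logit = np.log(base / (1.0 - base))
    if spec.co_drugs:
        logit = logit + co_mat @ np.log([d.odds_multiplier for d in spec.co_drugs])
    p_event = 1.0 / (1.0 + np.exp(-logit))
    has_r = rng.random(n) < p_event
    distractors = rng.integers(0, len(DISTRACTOR_VOCABULARY), size=(n, N_DISTRACTOR_REACTIONS))

    # variants of each drug's verbatim string, from the synonym table
    variants_of: dict[str, list[str]] = {}
    for verbatim, atc in spec.synonym_table.items():
        variants_of.setdefault(atc, []).append(verbatim)
    for atc in variants_of:
        variants_of[atc].sort()

    dup = rng.random(n) < spec.duplicate_frac
    perturb = dup & (rng.random(n) < 0.5)
    perturb_drug = rng.integers(0, max(len(spec.co_drugs), 1), size=n)

    demo_rows: list[tuple[str, str, str]] = []
    drug_rows: list[tuple[str, str]] = []
    reac_rows: list[tuple[str, str]] = []

    def emit(pid: str, case_idx: int, drug_mask: np.ndarray, include_a: bool) -> None:
        if include_a:
            names = variants_of[spec.drug_a_atc]
            drug_rows.append((pid, names[rng.integers(0, len(names))]))
        for k in np.flatnonzero(drug_mask):
            names = variants_of[spec.co_drugs[k].atc_code]
            drug_rows.append((pid, names[rng.integers(0, len(names))]))
        if has_r[case_idx]:
            reac_rows.append((pid, INDEXED_REACTION))
        for d in distractors[case_idx]:
            reac_rows.append((pid, DISTRACTOR_VOCABULARY[d]))

    for i in range(n):
        caseid = str(i + 1)
        final_version = 2 if dup[i] else 1
        if dup[i]:
            mask = co_mat[i].copy()
            if perturb[i] and mask.size:
                j = perturb_drug[i]
                mask[j] = ~mask[j]
            pid = f"{caseid}01"
            demo_rows.append((pid, caseid, "1"))
            emit(pid, i, mask, bool(has_a[i]))
        pid = f"{caseid}0{final_version}"
        demo_rows.append((pid, caseid, str(final_version)))
        emit(pid, i, co_mat[i], bool(has_a[i]))

    demo = pd.DataFrame(demo_rows, columns=["primaryid", "caseid", "caseversion"])
    drug = pd.DataFrame(drug_rows, columns=["primaryid", "drugname"])
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"])

    atc_codes = [d.atc_code for d in spec.co_drugs]
    truth = {
        "indexed_reaction": INDEXED_REACTION,
        "drug_a_atc": spec.drug_a_atc,
        "n_cases": n,
        "cases": {
            str(i + 1): {
                "drugs": sorted(
                    ([spec.drug_a_atc] if has_a[i] else []) + [atc_codes[k] for k in np.flatnonzero(co_mat[i])]
                ),
                "has_reaction": bool(has_r[i]),
            }
            for i in range(n)
        },
        "protective_drugs": sorted(d.atc_code for d in spec.co_drugs if d.odds_multiplier < 1),
        "risk_drugs": sorted(d.atc_code for d in spec.co_drugs if d.odds_multiplier > 1),
        "null_drugs": sorted(d.atc_code for d in spec.co_drugs if d.odds_multiplier == 1),
    }
    return demo, drug, reac, truth


# ---------------------------------------------------------------------------
# perturbagen signature library
# ---------------------------------------------------------------------------


@dataclass
class LibrarySimSpec:
    """Planted-reverser/mimicker score-library simulation."""

    n_perturbagens: int = 200
    n_genes: int = 1000
    n_reversers: int = 5
    n_mimickers: int = 5
    reversal_strength: float = 0.8
    noise_sd: float = 1.0
    reverser_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.reverser_names = tuple(self.reverser_names)
        _validate(self.n_perturbagens >= 1, "n_perturbagens", "must be >= 1")
        _validate(self.n_genes >= 2, "n_genes", "must be >= 2")
        _validate(self.n_reversers >= 0 and self.n_mimickers >= 0, "n_reversers", "must be >= 0")
        _validate(
            self.n_reversers + self.n_mimickers <= self.n_perturbagens,
            "n_reversers",
            "reversers + mimickers exceed perturbagens",
        )
        _validate(0 < self.reversal_strength <= 1, "reversal_strength", "must be in (0, 1]")
        _validate(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _validate(len(self.reverser_names) <= self.n_reversers, "reverser_names", "more names than reversers")


def simulate_signature_library(
    spec: LibrarySimSpec,
    query: GeneSignature,
) -> tuple[ReferenceSignatureLibrary, dict]:
    """Plant reversers and mimickers of ``query`` in a noise library.

    Background perturbagens get i.i.d. N(0, noise_sd) scores.  Reversers
    subtract ``reversal_strength * 3.0`` from query-up genes and add it to
    query-down genes; mimickers do the opposite.  Named reversers (e.g. a
    drug identity shared with the adverse-event simulation) take the first
    reverser slots.
    """
    universe = human_gene_universe(spec.n_genes)
    missing = sorted(query.genes - set(universe))
    if missing:
        raise ValueError(f"query genes outside library universe: {missing[:10]}")
    rng = np.random.default_rng(spec.seed)
    scores = rng.normal(0.0, spec.noise_sd, size=(spec.n_perturbagens, spec.n_genes))

    up_mask = np.isin(np.asarray(universe, dtype=object), sorted(query.up))
    down_mask = np.isin(np.asarray(universe, dtype=object), sorted(query.down))
    shift = spec.reversal_strength * LIBRARY_SHIFT_SCALE
    for i in range(spec.n_reversers):
        scores[i, up_mask] -= shift
        scores[i, down_mask] += shift
    for i in range(spec.n_reversers, spec.n_reversers + spec.n_mimickers):
        scores[i, up_mask] += shift
        scores[i, down_mask] -= shift

    names = []
    labels = {}
    for i in range(spec.n_perturbagens):
        if i < len(spec.reverser_names):
            name = spec.reverser_names[i]
            label = "reverser"
        elif i < spec.n_reversers:
            name, label = f"reverser-{i + 1:03d}", "reverser"
        elif i < spec.n_reversers + spec.n_mimickers:
            name, label = f"mimicker-{i + 1:03d}", "mimicker"
        else:
            name, label = f"chem-{i + 1:03d}", "background"
        names.append(name)
        labels[name] = label

    lib = ReferenceSignatureLibrary(names, universe, scores)
    truth = {
        "labels": labels,
        "reversers": [n for n in names if labels[n] == "reverser"],
        "mimickers": [n for n in names if labels[n] == "mimicker"],
    }
    return lib, truth
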