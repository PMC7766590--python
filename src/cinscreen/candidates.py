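"""Candidate nomination: harmonize and intersect the two screens.

The connectivity screen yields perturbagen names with negative tau; the
pharmacovigilance screen yields ATC level-5 codes with protective RORs.
A user-supplied (or simulated) name -> ATC mapping table bridges the two
identity spaces; candidates supported by both screens are ranked first.

``run_pipeline`` orchestrates the full analysis — signature construction,
connectivity query, adverse-event screen, and the final intersection —
from a config that either names input files or requests simulation, and
writes every intermediate artifact plus a JSON summary and a run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import connectivity as conn
from . import faers_screen as faers
from . import io as _io
from . import signature as sigmod
from . import synthetic_data as sim

__all__ = [
    "CandidateDrug",
    "IdentitySpace",
    "harmonize_names",
    "intersect_candidates",
    "run_pipeline",
    "default_config",
]

logger = logging.getLogger("cinscreen")

#: salt/formulation suffixes stripped during perturbagen-name normalization
DEFAULT_SALT_SUFFIXES = (
    "hydrochloride",
    "hcl",
    "sodium",
    "sulfate",
    "mesylate",
    "maleate",
    "citrate",
    "tartrate",
    "phosphate",
    "acetate",
)


@dataclass
class CandidateDrug:
    canonical_name: str
    atc_code: str | None
    tau: float | None
    ror_result: faers.RorResult | None
    sources: frozenset

    def __post_init__(self) -> None:
        self.sources = frozenset(self.sources)
        if not self.sources:
            raise ValueError("candidate needs at least one source")
        if not self.sources <= {"connectivity", "faers"}:
            raise ValueError(f"unknown sources: {self.sources}")

    @property
    def in_both(self) -> bool:
        return self.sources == {"connectivity", "faers"}


@dataclass
class IdentitySpace:
    """Aligned identity space keyed by ATC where mappable, else by name."""

    atc_of_name: dict[str, str] = field(default_factory=dict)
    name_of_atc: dict[str, str] = field(default_factory=dict)
    salt_suffixes: tuple[str, ...] = DEFAULT_SALT_SUFFIXES

    def normalize(self, name: str) -> str:
        norm = " ".join(name.strip().lower().split())
        parts = norm.split(" ")
        while len(parts) > 1 and parts[-1] in self.salt_suffixes:
            parts = parts[:-1]
        return " ".join(parts)

    def key_for_name(self, name: str) -> tuple[str, str]:
        """Identity key (kind, value) for a connectivity perturbagen name."""
        norm = self.normalize(name)
        atc = self.atc_of_name.get(norm)
        return ("atc", atc) if atc else ("name", norm)


def harmonize_names(
    connectivity_names: Sequence[str],
    faers_atc_codes: Sequence[str],
    mapping_table: Mapping[str, str],
) -> IdentitySpace:
    """Build the aligned identity space from a name -> ATC mapping table.

    Mapping is many-to-one (several perturbagen names may share one code);
    unmappable names remain connectivity-only identities keyed by their
    normalized name.
    """
    space = IdentitySpace()
    for name, atc in mapping_table.items():
        norm = space.normalize(name)
        space.atc_of_name[norm] = atc
        space.name_of_atc.setdefault(atc, norm)
    for name in connectivity_names:
        norm = space.normalize(name)
        if norm in space.atc_of_name:
            space.name_of_atc.setdefault(space.atc_of_name[norm], norm)
    for atc in faers_atc_codes:
        space.name_of_atc.setdefault(atc, atc)
    return space


def intersect_candidates(
    connectivity_selection: Sequence[conn.ConnectivityResult],
    faers_protective: Sequence[faers.RorResult],
    identity_space: IdentitySpace,
) -> list[CandidateDrug]:
    """Merge the two screens' selections into annotated candidates.

    Candidates supported by both screens come first, ordered by (tau
    ascending, CI upper bound ascending); then connectivity-only by tau,
    then pharmacovigilance-only by CI upper bound.
    """
    merged: dict[tuple[str, str], CandidateDrug] = {}
    for r in connectivity_selection:
        key = identity_space.key_for_name(r.perturbagen)
        atc = key[1] if key[0] == "atc" else None
        name = identity_space.name_of_atc.get(atc, identity_space.normalize(r.perturbagen)) if atc else identity_space.normalize(r.perturbagen)
        cur = merged.get(key)
        if cur is None or (cur.tau is not None and r.tau < cur.tau):
            merged[key] = CandidateDrug(name, atc, r.tau, None, frozenset({"connectivity"}))
    for r in faers_protective:
        key = ("atc", r.drug)
        name = identity_space.name_of_atc.get(r.drug, r.drug)
        cur = merged.get(key)
        if cur is None:
            merged[key] = CandidateDrug(name, r.drug, None, r, frozenset({"faers"}))
        else:
            merged[key] = CandidateDrug(cur.canonical_name, r.drug, cur.tau, r, cur.sources | {"faers"})

    def sort_key(c: CandidateDrug):
        rank = 0 if c.in_both else (1 if "connectivity" in c.sources else 2)
        tau = c.tau if c.tau is not None else float("inf")
        ci = c.ror_result.ci_high if c.ror_result is not None else float("inf")
        return (rank, tau, ci, c.canonical_name)

    return sorted(merged.values(), key=sort_key)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


def default_config(seed: int = 0) -> dict:
    """Fully-simulated scenario: one identity is planted as both a
    transcriptional reverser and a protective co-medication."""
    return {
        "seed": seed,
        "fdr": 0.01,
        "tau_threshold": 0.0,
        "drug_a": "L01XA01",
        "reaction": sim.INDEXED_REACTION,
        "min_exposed": 3,
        "simulate": {
            "transcriptome": {},
            "library": {"n_genes": 2000, "reverser_names": ["palonosetron"]},
            "faers": {},
        },
        "name_to_atc": {"palonosetron": "A04AA05", "gentamicin": "J01GB03"},
    }


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Execute signature -> connectivity and adverse-event screen -> candidates.

    Stages run from simulated or file inputs per the config; every
    intermediate artifact is written under ``out_dir`` along with
    ``summary.json`` and ``run.log``.  A missing adverse-event input yields
    a connectivity-only report with null pharmacovigilance fields.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seed = int(config.get("seed", 0))
    cfg_hash = _config_hash(config)
    logger.info("pipeline start seed=%d config_hash=%s", seed, cfg_hash)

    try:
        summary: dict = {"seed": seed, "config_hash": cfg_hash}
        simulate = config.get("simulate") or {}
        fdr = float(config.get("fdr", 0.01))
        tau_threshold = float(config.get("tau_threshold", 0.0))

        # ----- signature stage -------------------------------------------
        stage = "signature"
        try:
            if "transcriptome" in simulate:
                t_spec = sim.TranscriptomeSimSpec.with_planted(seed=seed, **simulate["transcriptome"])
                datasets, ortho, t_truth = sim.simulate_count_datasets(t_spec)
                (out / "truth_transcriptome.json").write_text(json.dumps(t_truth, indent=1))
            else:
                inputs = config["inputs"]
                datasets = []
                for i, (cp, lp) in enumerate(zip(inputs["counts"], inputs["labels"])):
                    cdf = _io.read_counts_tsv(cp)
                    labels = _io.read_labels_tsv(lp)
                    species = inputs.get("species", ["human"] * len(inputs["counts"]))[i]
                    datasets.append(
                        sigmod.CountDataset(
                            Path(cp).stem, list(cdf.index), list(cdf.columns),
                            cdf.to_numpy().astype(int), labels, species,
                        )
                    )
                ortho = _io.read_ortholog_tsv(inputs["orthologs"]) if inputs.get("orthologs") else []
            sig, de_results, reports = sigmod.build_signature(datasets, ortho, fdr=fdr)
            _io.write_signature_gmt(out / "signature.gmt", "SIGNATURE", sig.up, sig.down)
            (out / "signature.json").write_text(
                json.dumps({"up": sorted(sig.up), "down": sorted(sig.down), "provenance": sig.provenance}, indent=1)
            )
            summary["signature"] = {"n_up": len(sig.up), "n_down": len(sig.down)}
            logger.info("signature: %d up / %d down", len(sig.up), len(sig.down))
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        # ----- connectivity stage ----------------------------------------
        stage = "connectivity"
        try:
            if "library" in simulate:
                l_spec = sim.LibrarySimSpec(seed=seed + 1, **simulate["library"])
                lib, l_truth = sim.simulate_signature_library(l_spec, sig)
                (out / "truth_library.json").write_text(json.dumps(l_truth, indent=1))
            else:
                lib = conn.ReferenceSignatureLibrary.from_frame(_io.read_gct(config["inputs"]["library"]).T)
            results, selection = conn.query_library(sig, lib, tau_threshold)
            conn.results_to_frame(results).to_csv(out / "connectivity.tsv", sep="\t", index=False)
            summary["connectivity"] = {"n_scored": len(results), "n_selected": len(selection)}
            logger.info("connectivity: %d scored, %d selected at tau<%g", len(results), len(selection), tau_threshold)
            selected_results = [r for r in results if r.perturbagen in set(selection)]
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        # ----- adverse-event screen --------------------------------------
        stage = "faers_screen"
        protective: list[faers.RorResult] = []
        have_faers = "faers" in simulate or bool(config.get("inputs", {}).get("faers_demo"))
        if have_faers:
            try:
                drug_a = config.get("drug_a", "L01XA01")
                reaction = config.get("reaction", sim.INDEXED_REACTION)
                min_exposed = int(config.get("min_exposed", 3))
                if "faers" in simulate:
                    f_spec = sim.FaersSimSpec(seed=seed + 2, **simulate["faers"])
                    demo, drug, reac, f_truth = sim.simulate_faers_tables(f_spec)
                    synonyms = dict(f_spec.synonym_table)
                    (out / "truth_faers.json").write_text(
                        json.dumps({k: v for k, v in f_truth.items() if k != "cases"}, indent=1)
                    )
                    cases, _ = faers.cases_from_tables(demo, drug, reac)
                else:
                    inputs = config["inputs"]
                    cases, _ = faers.read_faers_tables(inputs["faers_demo"], inputs["faers_drug"], inputs["faers_reac"])
                    synonyms = _io.read_synonym_tsv(inputs["synonyms"])
                deduped = faers.deduplicate_cases(cases)
                collated, unmapped = faers.collate_to_atc(deduped, synonyms)
                cohort = faers.build_cohort(collated, drug_a)
                screen = faers.screen_comedications(cohort, reaction, min_exposed, drug_a=drug_a)
                faers.results_to_frame(screen).to_csv(out / "faers_screen.tsv", sep="\t", index=False)
                protective = [r for r in screen if r.protective]
                summary["faers"] = {
                    "n_cases": len(deduped),
                    "n_cohort": len(cohort),
                    "n_screened": len(screen),
                    "n_protective": len(protective),
                }
                logger.info("faers: cohort %d, %d screened, %d protective", len(cohort), len(screen), len(protective))
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        else:
            summary["faers"] = None
            logger.info("faers inputs absent: connectivity-only report")

        # ----- candidate intersection ------------------------------------
        stage = "candidates"
        try:
            mapping = dict(config.get("name_to_atc", {}))
            space = harmonize_names([r.perturbagen for r in selected_results], [r.drug for r in protective], mapping)
            cands = intersect_candidates(selected_results, protective, space)
            rows = [
                {
                    "canonical_name": c.canonical_name,
                    "atc_code": c.atc_code or "",
                    "tau": "" if c.tau is None else f"{c.tau:.4f}",
                    "ror": "" if c.ror_result is None else f"{c.ror_result.ror:.4f}",
                    "ci_high": "" if c.ror_result is None else f"{c.ror_result.ci_high:.4f}",
                    "sources": "+".join(sorted(c.sources)),
                }
                for c in cands
            ]
            with open(out / "candidates.tsv", "w", encoding="utf-8", newline="\n") as fh:
                cols = ["canonical_name", "atc_code", "tau", "ror", "ci_high", "sources"]
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(row[c] for c in cols) + "\n")
            in_both = sorted(c.canonical_name for c in cands if c.in_both)
            summary["candidates"] = {
                "n_total": len(cands),
                "in_both": in_both,
                "n_protective": None if summary["faers"] is None else summary["faers"]["n_protective"],
            }
            logger.info("candidates: %d total, in both screens: %s", len(cands), in_both or "none")
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        logger.info("pipeline done")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
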