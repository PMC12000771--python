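"""End-to-end orchestration: simulate → extract → summarize → associate →
cluster → report, with a reproducibility manifest.

Every stage writes its artifact as comma-separated UTF-8 text with a header
row; the manifest (JSON) records inputs, seeds, package version and a
SHA-256 checksum of every output, so a rerun with the same configuration
can be verified byte-for-byte with :func:`verify_bundle`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .association import associate_all, results_to_frame
from .clustering import (
    build_feature_matrix,
    characterize_clusters,
    cluster_outcome_risk,
    elbow_select_k,
    kmeans_fit,
)
from .extraction import ExtractionConfig, extract_cohort
from .lexicon import (
    MorbidityLexicon,
    default_complication_lexicon,
    default_morbidity_lexicon,
    load_lexicon,
)
from .summary import burden_distribution, stratified_table
from .synthetic import SimulationConfig, generate_cohort
from .textproc import clean_text, default_stopwords, remove_stopwords, term_frequencies, tokenize

logger = logging.getLogger("pregmorb.pipeline")

OUTCOME_COLUMNS = (
    "gdm", "preeclampsia", "pih", "preterm", "induction", "cesarean",
    "birth_defect", "scn_nicu", "shoulder_dystocia", "macrosomia",
)


@dataclass
class PipelineConfig:
    """Paths and options for a full pipeline run."""

    input_path: Path | None = None  # None -> simulate a cohort
    lexicon_path: Path | None = None  # None -> shipped default
    output_dir: Path = Path("pregmorb_out")
    simulation: SimulationConfig | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    exposures: Sequence[str] | None = None  # None -> all conditions + derived
    outcomes: Sequence[str] | None = None  # None -> available outcome columns
    feature_mode: str = "binary"
    k_min: int = 1
    k_max: int = 8
    override_k: int | None = None
    seed: int = 0
    n_init: int = 10
    top_n_terms: int = 25
    top_k_associations: int = 40


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _outcome_frame(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Structured 0/1 outcome columns, or extraction from complications text."""
    present = [c for c in OUTCOME_COLUMNS if c in records.columns]
    if present:
        return records[["record_id", *present]].copy()
    comp_lex = default_complication_lexicon()
    comp_profiles = extract_cohort(
        records, comp_lex, config.extraction, text_column="complications_text"
    )
    cols = ["record_id", *comp_lex.condition_ids]
    return comp_profiles[cols]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the manifest dict.

    Fails fast — a missing lexicon or input path aborts before any stage
    runs; a stage failure is logged with the stage name and re-raised, and
    a ``FAILED`` marker is left next to any partial outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.lexicon_path is not None and not Path(config.lexicon_path).exists():
        raise FileNotFoundError(f"lexicon path does not exist: {config.lexicon_path}")
    if config.input_path is not None and not Path(config.input_path).exists():
        raise FileNotFoundError(f"input path does not exist: {config.input_path}")
    lexicon: MorbidityLexicon = (
        load_lexicon(config.lexicon_path)
        if config.lexicon_path is not None
        else default_morbidity_lexicon()
    )

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "input_path": str(config.input_path) if config.input_path else None,
            "lexicon_path": str(config.lexicon_path) if config.lexicon_path else None,
            "simulated": config.input_path is None,
        },
        "stages": {},
        "outputs": {},
    }
    stage = "startup"
    try:
        # -- simulate / load ------------------------------------------------
        stage = "simulate" if config.input_path is None else "load"
        t0 = time.perf_counter()
        if config.input_path is None:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            records, truth = generate_cohort(sim, morbidity_lexicon=lexicon)
            _write(records, out / "cohort.csv")
            _write(truth, out / "ground_truth.csv")
        else:
            records = pd.read_csv(config.input_path)
        manifest["stages"][stage] = {
            "n_records": len(records),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("%s: %d records", stage, len(records))

        # -- term frequencies ----------------------------------------------
        stage = "term_frequencies"
        t0 = time.perf_counter()
        stop = default_stopwords()
        docs = [
            remove_stopwords(tokenize(clean_text(str(t) if not pd.isna(t) else "")), stop)
            for t in records["medical_conditions_text"]
        ]
        tf = term_frequencies(docs, config.top_n_terms) if any(docs) else []
        _write(pd.DataFrame(tf, columns=["term", "count"]), out / "term_frequencies.csv")
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        # -- extract --------------------------------------------------------
        stage = "extract"
        t0 = time.perf_counter()
        profiles = extract_cohort(records, lexicon, config.extraction)
        _write(profiles, out / "profiles.csv")
        manifest["stages"][stage] = {
            "n_profiles": len(profiles),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # -- summarize ------------------------------------------------------
        stage = "summarize"
        t0 = time.perf_counter()
        dist = burden_distribution(profiles)
        _write(dist.to_frame(), out / "burden_distribution.csv")
        for var in ("maternal_age", "bmi"):
            _write(
                stratified_table(profiles, records, var), out / f"burden_by_{var}.csv"
            )
        manifest["stages"][stage] = {
            "multimorbidity_percent": dist.percent_multimorbidity,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # -- associate ------------------------------------------------------
        stage = "associate"
        t0 = time.perf_counter()
        outcome_frame = _outcome_frame(records, config)
        exposures = list(config.exposures or
                         [*lexicon.condition_ids, "overweight", "obesity", "advanced_age"])
        outcomes = list(config.outcomes or
                        [c for c in outcome_frame.columns if c != "record_id"])
        results = associate_all(profiles, outcome_frame, exposures, outcomes)
        _write(results_to_frame(results), out / "associations.csv")
        n_degenerate = sum(r.degenerate for r in results)
        if n_degenerate:
            logger.warning("%d degenerate association pair(s)", n_degenerate)
        manifest["stages"][stage] = {
            "n_pairs": len(results),
            "n_degenerate": n_degenerate,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # -- cluster --------------------------------------------------------
        stage = "cluster"
        t0 = time.perf_counter()
        fm = build_feature_matrix(profiles, mode=config.feature_mode)
        curve = elbow_select_k(
            fm, config.k_min, config.k_max,
            seed=config.seed, n_init=config.n_init, override_k=config.override_k,
        )
        model = kmeans_fit(fm, curve.chosen_k, seed=config.seed, n_init=config.n_init)
        _write(curve.to_frame(), out / "elbow_curve.csv")
        _write(
            pd.DataFrame({"record_id": fm.record_ids, "cluster": model.assignments}),
            out / "cluster_assignments.csv",
        )
        chars = characterize_clusters(model, profiles)
        _write(
            pd.DataFrame(
                [
                    {"cluster": cl, "rank": i + 1, "condition": c, "prevalence": p}
                    for cl, items in chars.items()
                    for i, (c, p) in enumerate(items)
                ]
            ),
            out / "cluster_profiles.csv",
        )
        if "gdm" in outcome_frame.columns:
            risk = cluster_outcome_risk(model, outcome_frame["gdm"].to_numpy())
            _write(risk.to_frame(), out / "cluster_gdm_risk.csv")
            _write(
                risk.pairwise_p.reset_index(names="cluster"),
                out / "cluster_gdm_pairwise_p.csv",
            )
        manifest["stages"][stage] = {
            "chosen_k": curve.chosen_k,
            "inertia": model.inertia,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise

    for p in sorted(out.glob("*.csv")):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def verify_bundle(output_dir: Path | str) -> dict[str, bool]:
    """Recompute checksums of a bundle's artifacts against its manifest."""
    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return {
        name: (out / name).exists() and _sha256(out / name) == digest
        for name, digest in manifest["outputs"].items()
    }
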