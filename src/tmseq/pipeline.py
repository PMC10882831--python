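"""End-to-end pipeline: simulate → collapse → call → spectrum → report.

A *scenario* (YAML file, builtin name, or dict) declares a reference, one
or more condition groups with per-replicate simulation parameters, and
analysis settings. Running it produces a report directory of TSVs, a run
log with versions/seeds/parameters, a MANIFEST, and a plain-text summary
with the group rate comparison.

Two execution engines produce identical results (asserted by the test
suite): ``records`` materializes FASTQ and runs the full read-level
pipeline; ``sparse`` uses the event-level engine and is the right choice
for large parameter-recovery runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._seq import parse_sub, sub_label
from .calling import (
    call_discrepancies,
    classify_calls,
    error_spectrum,
    write_calls_tsv,
)
from .cirseq import cirseq_error_rate, fold_fastq
from .consensus import collapse_families, group_families, read_fastq, write_consensus_tsv
from .engine import collapse_and_call
from .pseudoallele import (
    compute_pseudo_alleles,
    ratio_histogram,
    write_pseudo_alleles_tsv,
)
from .reference import ReferenceSet
from .simulate import SimulatedCells, SimulationConfig, simulate_cirseq
from .stats import SampleGroup, compare_groups, group_mean_rates

logger = logging.getLogger(__name__)

#: Bundled demonstration scenario: quiescent neural-stem-cell-like
#: transcriptome, three genotoxin-treated and three vehicle replicates.
#: Treated cells carry single-allele fully-miscoding C→T lesions on top of
#: the vehicle background; injected so the treated C→U molecule-error rate
#: is 6.9e-5 bp^-1 and the vehicle rate 6.7e-6 bp^-1 (background errors
#: are uniform over the 3 alt bases, so C→U gets one third of 2.01e-5).
MAM_DEMO: dict = {
    "name": "mam_demo",
    "seed": 1,
    "engine": "records",
    "reference": {"n_transcripts": 8, "length": 1200, "gc": 0.5},
    "consensus": {"min_reads": 2, "min_agreement": 1.0},
    "classification": {"mut_frac_threshold": 0.95, "min_mut_coverage": 10},
    "pseudo_alleles": {
        "min_fraction": 0.10,
        "min_mut_molecules": 2,
        "min_total_molecules": 10,
    },
    "spectrum": {"unit": "molecule"},
    "compare": {"type": "C>T", "welch": False},
    "groups": [
        {
            "label": "treated",
            "replicates": 3,
            "simulation": {
                "n_cells": 60,
                "molecules_per_cell_per_transcript": 10.0,
                "reads_per_molecule": 3.0,
                "min_reads_per_molecule": 2,
                "lesion_site_rate": 1.246e-4,
                "lesion_miscoding_prob": 1.0,
                "lesioned_allele_fraction": 0.5,
                "background_tx_error_rate": 2.01e-5,
                "pcr_error_rate": 1e-6,
                "pcr_cycles": 12,
                "seq_error_rate": 1e-3,
            },
        },
        {
            "label": "vehicle",
            "replicates": 3,
            "simulation": {
                "n_cells": 60,
                "molecules_per_cell_per_transcript": 10.0,
                "reads_per_molecule": 3.0,
                "min_reads_per_molecule": 2,
                "lesion_site_rate": 0.0,
                "background_tx_error_rate": 2.01e-5,
                "pcr_error_rate": 1e-6,
                "pcr_cycles": 12,
                "seq_error_rate": 1e-3,
            },
        },
    ],
    "cirseq": {
        "repeat_count": 3,
        "fragment_length": 100,
        "min_period": 80,
        "max_period": 120,
        "groups": [
            {
                "label": "treated",
                "replicates": 1,
                "simulation": {
                    "cirseq_fragments": 1500,
                    "background_tx_error_rate": 1e-4,
                    "seq_error_rate": 1e-3,
                },
            },
            {
                "label": "vehicle",
                "replicates": 1,
                "simulation": {
                    "cirseq_fragments": 1500,
                    "background_tx_error_rate": 1e-5,
                    "seq_error_rate": 1e-3,
                },
            },
        ],
    },
}

SCENARIOS = {"mam_demo": MAM_DEMO}

ZERO_ERROR_DEMO: dict = {
    "name": "zero_error",
    "seed": 0,
    "engine": "records",
    "reference": {"n_transcripts": 3, "length": 400, "gc": 0.5},
    "compare": {"type": "C>T"},
    "groups": [
        {"label": "a", "replicates": 2, "simulation": {"n_cells": 5}},
        {"label": "b", "replicates": 2, "simulation": {"n_cells": 5}},
    ],
}
SCENARIOS["zero_error"] = ZERO_ERROR_DEMO


def load_scenario(source) -> dict:
    """Resolve a scenario from a builtin name, YAML path, or dict."""
    if isinstance(source, dict):
        return source
    if str(source) in SCENARIOS:
        return SCENARIOS[str(source)]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"scenario {source!r} is neither a builtin "
            f"({', '.join(sorted(SCENARIOS))}) nor an existing file"
        )
    return yaml.safe_load(path.read_text())


def _child_seed(root: np.random.SeedSequence) -> int:
    return int(root.spawn(1)[0].generate_state(1)[0] % (2**31))


def _build_reference(spec: dict, seed: int) -> ReferenceSet:
    if "fasta" in spec:
        path = Path(spec["fasta"])
        if not path.exists():
            raise FileNotFoundError(f"reference FASTA not found: {path}")
        return ReferenceSet.from_fasta(path)
    return ReferenceSet.random(
        n_transcripts=int(spec.get("n_transcripts", 8)),
        length=int(spec.get("length", 1200)),
        gc=float(spec.get("gc", 0.5)),
        seed=seed,
    )


def _run_scrna_replicate(
    label: str,
    rep: int,
    cfg: SimulationConfig,
    reference: ReferenceSet,
    scenario: dict,
    outdir: Path,
    engine: str,
    manifest_files: list[str],
):
    cons_p = scenario.get("consensus", {})
    cls_p = scenario.get("classification", {})
    pa_p = scenario.get("pseudo_alleles", {})
    unit = scenario.get("spectrum", {}).get("unit", "molecule")
    sample_id = f"{label}_rep{rep}"
    sim = SimulatedCells.generate(cfg, reference)
    truth_path = outdir / f"{sample_id}.truth.tsv"
    sim.truth.to_tsv(truth_path)
    manifest_files.append(truth_path.name)

    if engine == "records":
        fastq = outdir / f"{sample_id}.fastq"
        sim.write_fastq(fastq)
        manifest_files.append(fastq.name)
        families = group_families(read_fastq(fastq))
        molecules, tally = collapse_families(
            families,
            min_reads=int(cons_p.get("min_reads", 2)),
            min_agreement=float(cons_p.get("min_agreement", 1.0)),
        )
        cons_path = outdir / f"{sample_id}.consensus.tsv"
        write_consensus_tsv(molecules, cons_path)
        manifest_files.append(cons_path.name)
        calls = call_discrepancies(molecules, reference)
        classify_calls(
            calls,
            mut_frac_threshold=float(cls_p.get("mut_frac_threshold", 0.95)),
            min_mut_coverage=int(cls_p.get("min_mut_coverage", 10)),
        )
        spectrum = error_spectrum(
            calls, molecules, reference, sample_id=sample_id, unit=unit
        )
        logger.info(
            "%s: %d reads in %d families -> %d molecules (rejected: %s)",
            sample_id,
            sum(len(v) for v in families.values()),
            len(families),
            len(molecules),
            tally or "none",
        )
    elif engine == "sparse":
        result = collapse_and_call(
            sim,
            min_reads=int(cons_p.get("min_reads", 2)),
            min_agreement=float(cons_p.get("min_agreement", 1.0)),
            mut_frac_threshold=float(cls_p.get("mut_frac_threshold", 0.95)),
            min_mut_coverage=int(cls_p.get("min_mut_coverage", 10)),
            sample_id=sample_id,
            unit=unit,
        )
        calls, spectrum = result.calls, result.spectrum
    else:
        raise ValueError(f"unknown engine {engine!r}")

    calls_path = outdir / f"{sample_id}.calls.tsv"
    write_calls_tsv(calls, calls_path)
    manifest_files.append(calls_path.name)
    spec_path = outdir / f"{sample_id}.spectrum.tsv"
    spectrum.to_tsv(spec_path)
    manifest_files.append(spec_path.name)

    pseudo = compute_pseudo_alleles(
        calls,
        min_fraction=float(pa_p.get("min_fraction", 0.10)),
        min_mut_molecules=int(pa_p.get("min_mut_molecules", 2)),
        min_total_molecules=int(pa_p.get("min_total_molecules", 10)),
    )
    pa_path = outdir / f"{sample_id}.pseudo_alleles.tsv"
    write_pseudo_alleles_tsv(pseudo, pa_path)
    manifest_files.append(pa_path.name)
    hist_path = outdir / f"{sample_id}.ratio_histogram.tsv"
    with open(hist_path, "w") as fh:
        fh.write("# tmseq mutant:WT ratio histogram; bins (low, high]\n")
        ratio_histogram(pseudo).to_csv(fh, sep="\t", index=False)
    manifest_files.append(hist_path.name)
    return spectrum, pseudo


def run_pipeline(
    scenario,
    outdir,
    seed: int | None = None,
    engine: str | None = None,
    log_level: str = "INFO",
) -> Path:
    """Execute a scenario end to end; returns the report directory.

    Fully reproducible from (scenario, seed): per-replicate seeds are
    spawned deterministically from the root seed. On a stage failure the
    MANIFEST marks the run incomplete and the exception propagates.
    """
    scenario = load_scenario(scenario)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(scenario.get("seed", 0)) if seed is None else int(seed)
    engine = engine or scenario.get("engine", "records")

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root_logger = logging.getLogger("tmseq")
    root_logger.addHandler(handler)
    root_logger.setLevel(getattr(logging, log_level.upper(), logging.INFO))

    manifest = {
        "scenario": scenario.get("name", "unnamed"),
        "tmseq_version": __version__,
        "seed": seed,
        "engine": engine,
        "status": "incomplete",
        "files": [],
    }
    files: list[str] = manifest["files"]

    def flush_manifest():
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")

    flush_manifest()
    try:
        logger.info(
            "run_pipeline: scenario=%s seed=%d engine=%s tmseq=%s",
            manifest["scenario"],
            seed,
            engine,
            __version__,
        )
        root_ss = np.random.SeedSequence(seed)
        reference = _build_reference(
            scenario.get("reference", {}), _child_seed(root_ss)
        )
        ref_path = outdir / "reference.fasta"
        reference.to_fasta(ref_path)
        files.append(ref_path.name)

        summary_lines = [
            f"tmseq pipeline summary — scenario '{manifest['scenario']}', "
            f"seed {seed}, engine {engine}",
            "",
        ]
        sub = parse_sub(scenario.get("compare", {}).get("type", "C>T"))
        welch = bool(scenario.get("compare", {}).get("welch", False))

        groups: list[SampleGroup] = []
        first_pseudo = None
        for gspec in scenario["groups"]:
            label = gspec["label"]
            spectra = []
            for rep in range(1, int(gspec.get("replicates", 1)) + 1):
                cfg = SimulationConfig(
                    **gspec.get("simulation", {}), seed=_child_seed(root_ss)
                )
                spectrum, pseudo = _run_scrna_replicate(
                    label, rep, cfg, reference, scenario, outdir, engine, files
                )
                spectra.append(spectrum)
                if first_pseudo is None and pseudo:
                    first_pseudo = (f"{label}_rep{rep}", pseudo)
            group = SampleGroup(label, spectra)
            groups.append(group)
            mean = group_mean_rates(group)[sub]
            summary_lines.append(
                f"group {label}: mean {sub_label(*sub, rna=True)} rate = "
                f"{mean:.3e} bp^-1 ({group.n_replicates} replicates)"
            )

        if len(groups) >= 2 and all(g.n_replicates >= 2 for g in groups[:2]):
            t, p = compare_groups(groups[0], groups[1], sub, welch=welch)
            summary_lines.append(
                f"unpaired two-tailed t-test ({sub_label(*sub, rna=True)}), "
                f"{groups[0].label} vs {groups[1].label}: t = {t:.3f}, p = {p:.3g}"
            )
        if first_pseudo is not None:
            sid, pseudo = first_pseudo
            fracs = np.array([p.mutant_fraction for p in pseudo])
            summary_lines.append(
                f"pseudo-alleles ({sid}): {len(pseudo)} reported; "
                f"median mutant fraction {np.median(fracs):.2f}"
            )

        cir = scenario.get("cirseq")
        if cir:
            summary_lines.append("")
            for gspec in cir["groups"]:
                label = gspec["label"]
                for rep in range(1, int(gspec.get("replicates", 1)) + 1):
                    cfg = SimulationConfig(
                        **gspec.get("simulation", {}), seed=_child_seed(root_ss)
                    )
                    sample_id = f"cirseq_{label}_rep{rep}"
                    fastq = outdir / f"{sample_id}.fastq"
                    simulate_cirseq(
                        cfg,
                        reference,
                        int(cir["repeat_count"]),
                        int(cir["fragment_length"]),
                        fastq,
                    )
                    files.append(fastq.name)
                    consensi, tally = fold_fastq(
                        fastq,
                        min_period=int(cir.get("min_period", 2)),
                        max_period=int(cir.get("max_period", cir["fragment_length"] * 2)),
                    )
                    spec = cirseq_error_rate(consensi, reference, sample_id=sample_id)
                    spec_path = outdir / f"{sample_id}.spectrum.tsv"
                    spec.to_tsv(spec_path)
                    files.append(spec_path.name)
                    summary_lines.append(
                        f"cirseq {label} rep{rep}: overall N→N rate = "
                        f"{spec.overall_rate:.3e} bp^-1 "
                        f"({len(consensi)} folded reads; dropped {tally})"
                    )

        summary_path = outdir / "summary.txt"
        summary_path.write_text("\n".join(summary_lines) + "\n")
        files.append(summary_path.name)
        files.append("run.log")
        manifest["status"] = "complete"
        flush_manifest()
        logger.info("run_pipeline: complete, %d files in %s", len(files), outdir)
        return outdir
    except Exception:
        logger.exception("run_pipeline: stage failed; partial outputs retained")
        flush_manifest()
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def summarize_run(outdir) -> str:
    """Return the summary of a completed run directory."""
    outdir = Path(outdir)
    summary = outdir / "summary.txt"
    if not summary.exists():
        raise FileNotFoundError(f"no summary.txt in {outdir} (incomplete run?)")
    return summary.read_text()
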