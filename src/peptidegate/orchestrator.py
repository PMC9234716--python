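"""End-to-end screen: curate -> scan -> group -> propose -> map -> ephys stats.

Also houses the fixture-bundle writer, which materializes one coherent
synthetic study — alignment, trimer, dose-response tables and paired
traces — whose planted truths are the printed wild-type values the
statistics modules are expected to recover (EC50s of 3.4 µM, 350 nM, 2 µM
and 340 nM; potency ratio 0.64; fold-enhancement 10; 43 planted columns
including the six interface residues 231/281/288/316/447/529).

A single pipeline seed fans out to per-stage seeds by fixed offsets so any
stage can be re-run in isolation and reproduce its outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as pgio
from .sequence_curation import CurationConfig, curate
from .clade_contrast import (
    CladeLabeledAlignment,
    ScanConfig,
    group_vicinal,
    scan,
)
from .structure_mapping import TrimerStructure, detect_interface_residues
from .ephys_stats import (
    classify_mutants,
    enhancement_from_traces,
    fit_dose_response_set,
    potency_ratio_from_traces,
)
from .synthetic_data import (
    MsaSimConfig,
    simulate_dose_response,
    simulate_enhancement_pairs,
    simulate_msa,
    simulate_potency_pairs,
    simulate_trimer,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_screen", "make_fixture_bundle", "PipelineError",
           "FIXTURE_POCKET_RESIDUES", "FIXTURE_EC50S", "FIXTURE_RATIO", "FIXTURE_FOLD"]

# planted truths of the default fixture bundle: the study's wild-type values
FIXTURE_POCKET_RESIDUES = (231, 281, 288, 316, 447, 529)
FIXTURE_N_PLANTED = 43
FIXTURE_EC50S = {
    "aplysia_FaNaC_WT_FMRFa": 3.4e-6,
    "capitella_FaNaC_FMRFa": 350e-9,
    "capitella_WaNaC_AWVGDKSLSWa": 2e-6,
    "malacoceros_WaNaC_KWGGNSRMWa": 340e-9,
}
FIXTURE_RATIO = 0.64
FIXTURE_FOLD = 10.0

# per-stage seed offsets (fan-out from the single pipeline seed)
_SEED_OFFSETS = {
    "msa": 11,
    "trimer": 23,
    "dose_response": 31,
    "potency": 41,
    "enhancement": 47,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    alignment: str = ""
    clades: str = ""
    reference_id: str = ""
    structure: str = ""  # optional PDB
    dose_response_tables: dict[str, str] = field(default_factory=dict)
    potency_trace_dir: str = ""  # optional dir of paired two-pulse traces
    enhancement_trace_dir: str = ""
    out_dir: str = "screen_out"
    seed: int = 0
    run_curation: bool = True
    curation: CurationConfig = field(default_factory=CurationConfig)
    fg_conservation_min: float = 0.90
    bg_match_max: float = 0.20
    mode: str = "either"
    fg_gap_max: float = 0.50
    region_of_interest: tuple[tuple[int, int], ...] | None = None
    interface_cutoff: float = 8.0
    atom_mode: str = "CA"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cur = raw.pop("curation", None)
        cfg = cls(**raw)
        if cur:
            cfg.curation = CurationConfig(**cur)
        if cfg.region_of_interest is not None:
            cfg.region_of_interest = tuple(
                tuple(r) for r in cfg.region_of_interest
            )
        return cfg

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            reference_id=self.reference_id,
            fg_conservation_min=self.fg_conservation_min,
            bg_match_max=self.bg_match_max,
            mode=self.mode,
            fg_gap_max=self.fg_gap_max,
            region_of_interest=self.region_of_interest,
        )


def _stage(manifest: dict, name: str):
    """Context-style stage runner: logs timing, converts failures."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            manifest["stages"].setdefault(name, {})
            self.t0 = time.monotonic()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.monotonic() - self.t0
            if exc is not None:
                manifest["stages"].setdefault(name, {})["status"] = "failed"
                raise PipelineError(name, exc) from exc
            manifest["stages"].setdefault(name, {})["seconds"] = round(dt, 3)
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_screen(config: PipelineConfig) -> dict:
    """Run the full screen and write a manifest plus human-readable tables.

    Stages downstream of missing optional inputs are marked "skipped";
    any stage failure halts the run with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "stages": {},
    }

    with _stage(manifest, "load"):
        records = pgio.read_fasta(config.alignment)
        partition = pgio.read_clades_tsv(config.clades)
        if config.reference_id not in {r.id for r in records}:
            raise ValueError(
                f"reference id {config.reference_id!r} not in alignment"
            )

    if config.run_curation:
        with _stage(manifest, "curation"):
            report = curate(records, config.curation)
            kept_ids = {r.id for r in report.kept}
            if config.reference_id not in kept_ids:
                raise ValueError("curation removed the reference sequence")
            records = report.kept
            manifest["stages"]["curation"].update(
                n_kept=len(report.kept),
                n_removed_length=len(report.removed_length),
                n_removed_redundant=len(report.removed_redundant),
                redundancy_mapping=report.redundancy_mapping,
            )
            with open(out / "curation_removals.tsv", "w") as fh:
                fh.write("id\treason\tdetail\n")
                for row in report.removal_rows():
                    fh.write("\t".join(row) + "\n")
    else:
        manifest["stages"]["curation"] = {"status": "skipped"}

    with _stage(manifest, "scan"):
        partition = {r.id: partition[r.id] for r in records}
        aln = CladeLabeledAlignment(records, partition)
        candidates = scan(aln, config.scan_config())
        groups = group_vicinal(candidates)
        pgio.write_candidates_tsv(candidates, out / "candidates.tsv")
        manifest["stages"]["scan"].update(
            n_candidates=len(candidates),
            candidates=pgio.candidates_to_json(candidates),
            vicinal_groups=[[c.ref_number for c in g] for g in groups],
            proposed_mutations=[c.proposed_mutation for c in candidates],
        )

    if config.structure:
        with _stage(manifest, "structure"):
            structure = TrimerStructure.from_pdb(config.structure)
            report = detect_interface_residues(
                structure,
                [c.ref_number for c in candidates],
                cutoff=config.interface_cutoff,
                atom_mode=config.atom_mode,
            )
            manifest["stages"]["structure"].update(
                cutoff=report.cutoff,
                atom_mode=report.atom_mode,
                interfacial=report.flagged_res_ids,
                unresolved=report.unresolved,
                pockets=report.pockets,
            )
            with open(out / "pocket_report.tsv", "w") as fh:
                fh.write("chain\tres_id\tmin_interchain_A\tpartner\tinterfacial\n")
                for h in report.interfacial + report.non_interfacial:
                    fh.write(
                        f"{h.chain}\t{h.res_id}\t{h.distance:.3f}\t"
                        f"{h.partner_chain}\t{h.interfacial}\n"
                    )
    else:
        manifest["stages"]["structure"] = {"status": "skipped"}

    if config.dose_response_tables:
        with _stage(manifest, "hill_fits"):
            fits = {}
            for name, path in sorted(config.dose_response_tables.items()):
                res = fit_dose_response_set(pgio.read_dose_response(path, construct=name))
                fits[name] = res["summary"]
            manifest["stages"]["hill_fits"].update(summaries=fits)
    else:
        manifest["stages"]["hill_fits"] = {"status": "skipped"}

    for stage_name, trace_dir, fn, key in (
        ("potency_ratio", config.potency_trace_dir, potency_ratio_from_traces, "ratio"),
        ("enhancement", config.enhancement_trace_dir, enhancement_from_traces, "fold"),
    ):
        if trace_dir:
            with _stage(manifest, stage_name):
                paths = sorted(Path(trace_dir).glob("*.tsv"))
                traces = [pgio.read_trace(p) for p in paths]
                res = fn(traces)
                manifest["stages"][stage_name].update(
                    n=res.n, **{key: getattr(res, key), "sem": res.sem}
                )
        else:
            manifest["stages"][stage_name] = {"status": "skipped"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Fixture bundle


def default_planted_columns(seed: int, n_columns: int = 560) -> tuple[int, ...]:
    """43 planted columns: the six interface positions plus 37 drawn columns."""
    import numpy as np

    rng = np.random.default_rng(seed)
    fixed = set(FIXTURE_POCKET_RESIDUES)
    pool = [c for c in range(50, n_columns + 1) if c not in fixed]
    extra = rng.choice(pool, size=FIXTURE_N_PLANTED - len(fixed), replace=False)
    return tuple(sorted(fixed | {int(c) for c in extra}))


def make_fixture_bundle(seed: int, out_dir: str | Path) -> dict:
    """Write every synthetic input for a full screen run, plus truth.json.

    Returns a dict of paths and planted truths. All downstream stages run
    on this bundle should recover the planted values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    planted = default_planted_columns(seed + _SEED_OFFSETS["msa"])
    msa_cfg = MsaSimConfig(
        n_foreground=20,
        n_background=50,
        n_columns=560,
        planted_columns=planted,
        within_class_noise=0.0,
        n_redundant_duplicates=2,
        n_length_outliers=2,
        seed=seed + _SEED_OFFSETS["msa"],
    )
    aln, msa_truth = simulate_msa(msa_cfg)
    pgio.write_fasta(aln.records, out / "alignment.fasta")
    pgio.write_clades_tsv(aln.partition, out / "clades.tsv")
    unaligned = [
        type(r)(r.id, r.ungapped, r.description) for r in aln.records
    ] + msa_truth.outlier_records
    pgio.write_fasta(unaligned, out / "sequences_unaligned.fasta")

    structure, struct_truth = simulate_trimer(
        560, FIXTURE_POCKET_RESIDUES, interface_radius=5.0,
        seed=seed + _SEED_OFFSETS["trimer"],
    )
    structure.to_pdb(str(out / "trimer.pdb"))

    dr_paths = {}
    for i, (name, ec50) in enumerate(sorted(FIXTURE_EC50S.items())):
        ds, _ = simulate_dose_response(
            true_ec50=ec50,
            true_hill=1.0,
            true_imax=5.0,
            n_recordings=5,
            noise_sd_fraction=0.05,
            seed=seed + _SEED_OFFSETS["dose_response"] + i,
            construct=name,
        )
        path = out / f"dr_{name}.tsv"
        pgio.write_dose_response(ds, path)
        dr_paths[name] = str(path)

    ratio_dir = out / "potency_traces"
    ratio_dir.mkdir(exist_ok=True)
    traces, _ = simulate_potency_pairs(
        FIXTURE_RATIO, n_recordings=14, noise_sd_fraction=0.05,
        seed=seed + _SEED_OFFSETS["potency"],
    )
    for i, tr in enumerate(traces):
        pgio.write_trace(tr, ratio_dir / f"rec_{i + 1:03d}.tsv")

    enh_dir = out / "enhancement_traces"
    enh_dir.mkdir(exist_ok=True)
    traces, _ = simulate_enhancement_pairs(
        FIXTURE_FOLD, n_recordings=7, noise_sd_fraction=0.10,
        seed=seed + _SEED_OFFSETS["enhancement"],
    )
    for i, tr in enumerate(traces):
        pgio.write_trace(tr, enh_dir / f"rec_{i + 1:03d}.tsv")

    truth = {
        "seed": seed,
        "sdp_columns": list(msa_truth.sdp_columns),
        "duplicate_ids": msa_truth.duplicate_ids,
        "outlier_ids": list(msa_truth.outlier_ids),
        "pocket_residues": list(FIXTURE_POCKET_RESIDUES),
        "true_ec50_M": FIXTURE_EC50S,
        "true_ratio": FIXTURE_RATIO,
        "true_fold_enhancement": FIXTURE_FOLD,
        "reference_id": "fg_001",
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return {
        "alignment": str(out / "alignment.fasta"),
        "clades": str(out / "clades.tsv"),
        "unaligned": str(out / "sequences_unaligned.fasta"),
        "structure": str(out / "trimer.pdb"),
        "dose_response_tables": dr_paths,
        "potency_trace_dir": str(ratio_dir),
        "enhancement_trace_dir": str(enh_dir),
        "truth": truth,
    }
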