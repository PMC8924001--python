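"""End-to-end orchestration: simulate -> riboqc -> quantify -> te -> motif ->
enrich -> hdx -> fit-binding.

Configuration is a YAML file validated into :class:`RunConfig` (unknown keys
rejected).  Each stage records a key — the SHA-256 of its parameter block and
of its input files — in ``manifest.json``; a rerun with unchanged inputs
skips the stage, so identical config + seed reproduces identical outputs.
A single global seed is expanded into independent substreams for the four
simulator stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import annotation, binding, hdx, io, motifs, ribo, simulate, translatome
from .params import (SimBindingParams, SimHDXParams, SimRiboParams,
                     SimTranscriptomeParams, ThresholdSet)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "riboqc", "quantify", "te", "motif", "enrich", "hdx",
          "fit_binding")


class OffsetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    offset_window: int = Field(30, gt=0)
    min_reads_per_length: int = Field(50, gt=0)


class MotifConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    window: int = Field(10, gt=0)
    min_run: int = Field(5, gt=0)


class HdxAnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    delta_threshold: float = Field(0.5, gt=0)
    recovery: float = Field(0.8, gt=0, le=1)
    smoothing_window: int = Field(5, ge=1)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: Path = Path("ribopes_run")
    transcriptome: SimTranscriptomeParams = SimTranscriptomeParams()
    ribo: SimRiboParams = SimRiboParams()
    hdx_sim: SimHDXParams = SimHDXParams()
    binding_sim: SimBindingParams = SimBindingParams()
    thresholds: ThresholdSet = ThresholdSet()
    offsets: OffsetConfig = OffsetConfig()
    motif: MotifConfig = MotifConfig()
    hdx: HdxAnalysisConfig = HdxAnalysisConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(params_repr: str, inputs: list[Path]) -> str:
    h = hashlib.sha256(params_repr.encode())
    for p in sorted(inputs):
        h.update(p.name.encode())
        h.update(_sha256(p).encode())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        entry = self.data.get(stage)
        return (entry is not None and entry["key"] == key
                and all(Path(o).exists() for o in entry["outputs"]))

    def record(self, stage: str, key: str, outputs: list[Path]) -> None:
        self.data[stage] = {
            "key": key,
            "outputs": [str(o) for o in outputs],
            "checksums": {o.name: _sha256(o) for o in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2) + "\n")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in dependency order; returns the output dir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    seeds = simulate.substreams(config.seed, 4)
    tx_params = config.transcriptome.model_copy(update={"seed": seeds[0]})
    ribo_params = config.ribo.model_copy(update={"seed": seeds[1]})
    hdx_params = config.hdx_sim.model_copy(update={"seed": seeds[2]})
    bind_params = config.binding_sim.model_copy(update={"seed": seeds[3]})

    paths = {
        "fasta": out / "transcripts.fasta", "bed": out / "annotation.bed12",
        "counts": out / "counts.tsv", "truth_tx": out / "truth_transcripts.tsv",
        "truth_te": out / "truth_te.tsv", "hdx_csv": out / "hdx_state.csv",
        "protein": out / "protein.fasta", "hdx_truth": out / "truth_hdx.json",
        "binding": out / "binding.tsv",
    }

    if "simulate" in stages:
        key = _stage_key(tx_params.model_dump_json() + ribo_params.model_dump_json()
                         + hdx_params.model_dump_json() + bind_params.model_dump_json(), [])
        outputs = list(paths.values())
        if manifest.fresh("simulate", key, outputs):
            logger.info("simulate: inputs unchanged, skipping")
        else:
            models, truth = simulate.simulate_transcriptome(tx_params)
            annotation.write_fasta(models, paths["fasta"])
            annotation.write_bed12(models, paths["bed"])
            io.write_tsv(truth, paths["truth_tx"])
            profiles, te_truth = simulate.simulate_ribo_counts(models, truth, ribo_params)
            io.write_counts_tsv(profiles, paths["counts"])
            io.write_tsv(te_truth, paths["truth_te"])
            state, protein, hdx_truth = simulate.simulate_hdx(hdx_params)
            state.to_csv(paths["hdx_csv"], index=False)
            paths["protein"].write_text(f">protein\n{protein}\n")
            io.write_json({"protected_interval": hdx_truth["protected_interval"],
                           "protection_factor": hdx_truth["protection_factor"]},
                          paths["hdx_truth"])
            io.write_tsv(simulate.simulate_binding(bind_params), paths["binding"])
            manifest.record("simulate", key, outputs)
            logger.info("simulate: %d transcripts, %d libraries",
                        len(models), 2 * ribo_params.replicates * 2)

    models = annotation.models_by_id(
        annotation.read_bed12_fasta(paths["bed"], paths["fasta"]))
    profiles = None

    def _profiles():
        nonlocal profiles
        if profiles is None:
            profiles = io.read_counts_tsv(paths["counts"], models)
        return profiles

    conds = ribo_params.conditions
    offsets = None

    def _offsets():
        nonlocal offsets
        if offsets is None:
            rpf_libs = [lib for (c, r, a), lib in _profiles().items() if a == "rpf"]
            all_profiles = [p for lib in rpf_libs for p in lib.values()]
            offsets = ribo.estimate_psite_offsets(
                all_profiles, models,
                offset_window=config.offsets.offset_window,
                min_reads_per_length=config.offsets.min_reads_per_length)
        return offsets

    if "riboqc" in stages:
        key = _stage_key(config.offsets.model_dump_json(), [paths["counts"], paths["bed"]])
        out_json = out / "riboqc.json"
        if manifest.fresh("riboqc", key, [out_json]):
            logger.info("riboqc: unchanged, skipping")
        else:
            off = _offsets()
            report = {"offsets": {str(k): v for k, v in off.offsets.items()},
                      "global_offset": off.global_offset, "libraries": {}}
            for (cond, rep, assay), lib in sorted(_profiles().items()):
                if assay != "rpf":
                    continue
                per = ribo.periodicity_report(lib.values(), off, models)
                report["libraries"][f"{cond}_rep{rep}"] = {
                    "frame_fractions": list(per.frame_fractions),
                    "region_percent": dict(per.region_percent),
                    "n_psites_cds": per.n_psites_cds,
                }
            io.write_json(report, out_json)
            manifest.record("riboqc", key, [out_json])

    quant_paths = {
        (cond, rep, assay): out / f"quant_{cond}_rep{rep}_{assay}.tsv"
        for cond in conds for rep in range(1, ribo_params.replicates + 1)
        for assay in ("rpf", "rna")
    }
    if "quantify" in stages:
        key = _stage_key(config.offsets.model_dump_json() + "quant",
                         [paths["counts"], paths["bed"]])
        outputs = list(quant_paths.values())
        if manifest.fresh("quantify", key, outputs):
            logger.info("quantify: unchanged, skipping")
        else:
            off = _offsets()
            for (cond, rep, assay), lib in sorted(_profiles().items()):
                mode = "rpf_psite" if assay == "rpf" else "rna_fragment"
                q = ribo.quantify_regions(lib.values(), off, models, mode=mode)
                io.write_tsv(q, quant_paths[(cond, rep, assay)])
            manifest.record("quantify", key, outputs)

    te_path = out / "te_table.tsv"
    if "te" in stages:
        key = _stage_key(config.thresholds.model_dump_json(),
                         list(quant_paths.values()))
        run_manifest = out / "te_run_manifest.json"
        if manifest.fresh("te", key, [te_path, run_manifest]):
            logger.info("te: unchanged, skipping")
        else:
            rpf_q = {c: [io.read_tsv(quant_paths[(c, r, "rpf")])
                         for r in range(1, ribo_params.replicates + 1)] for c in conds}
            rna_q = {c: [io.read_tsv(quant_paths[(c, r, "rna")])
                         for r in range(1, ribo_params.replicates + 1)] for c in conds}
            te = translatome.compute_te(rpf_q, rna_q, conditions=conds,
                                        thresholds=config.thresholds)
            te = translatome.classify_translation(te, config.thresholds)
            io.write_tsv(te, te_path)
            io.write_json(json.loads(config.thresholds.model_dump_json()), run_manifest)
            manifest.record("te", key, [te_path, run_manifest])

    features_path = out / "utr_features.tsv"
    if "motif" in stages:
        key = _stage_key(config.motif.model_dump_json(), [paths["bed"], paths["fasta"]])
        if manifest.fresh("motif", key, [features_path]):
            logger.info("motif: unchanged, skipping")
        else:
            feats = motifs.utr_features(models.values(), window=config.motif.window,
                                        min_run=config.motif.min_run)
            io.write_tsv(feats, features_path)
            manifest.record("motif", key, [features_path])

    if "enrich" in stages:
        key = _stage_key(config.motif.model_dump_json(), [te_path, features_path])
        enrich_path = out / "enrichment.json"
        if manifest.fresh("enrich", key, [enrich_path]):
            logger.info("enrich: unchanged, skipping")
        else:
            te = io.read_tsv(te_path)
            feats = io.read_tsv(features_path)
            tested = te[te["translation_class"] != "low_coverage"]
            flags = feats.set_index("transcript_id")["pes_flag"].reindex(
                tested["transcript_id"]).fillna(False)
            up = tested.loc[tested["translation_class"] == "up_translated",
                            "transcript_id"].tolist()
            if up:
                res = motifs.hypergeometric_enrichment(flags, up).as_dict()
            else:
                res = {"N": int(len(flags)), "K": int(flags.sum()), "n": 0, "k": 0,
                       "p_hyper": None, "fold_enrichment": None,
                       "note": "no up-translated transcripts"}
            io.write_json(res, enrich_path)
            manifest.record("enrich", key, [enrich_path])

    if "hdx" in stages:
        key = _stage_key(config.hdx.model_dump_json(), [paths["hdx_csv"], paths["protein"]])
        uptake_path = out / "hdx_uptake.tsv"
        delta_path = out / "hdx_residue_delta.csv"
        calls_path = out / "hdx_residue_calls.csv"
        qc_path = out / "hdx_qc.json"
        outputs = [uptake_path, delta_path, calls_path, qc_path]
        if manifest.fresh("hdx", key, outputs):
            logger.info("hdx: unchanged, skipping")
        else:
            protein = "".join(
                line.strip() for line in paths["protein"].read_text().splitlines()
                if not line.startswith(">"))
            state = hdx.read_state_table(str(paths["hdx_csv"]))
            uptake = hdx.compute_uptake(state)
            io.write_tsv(uptake, uptake_path)
            deltas = hdx.differential_uptake(uptake,
                                             delta_threshold=config.hdx.delta_threshold)
            rmap = hdx.residue_delta_map(deltas, protein,
                                         smoothing_window=config.hdx.smoothing_window,
                                         delta_threshold=config.hdx.delta_threshold)
            rmap.values.to_csv(delta_path)
            rmap.calls.to_csv(calls_path)
            qc = hdx.hdx_qc(state.drop_duplicates("peptide_id"), len(protein))
            io.write_json(qc.as_dict(), qc_path)
            manifest.record("hdx", key, outputs)

    if "fit_binding" in stages:
        key = _stage_key("fit", [paths["binding"]])
        fit_path = out / "binding_fit.json"
        if manifest.fresh("fit_binding", key, [fit_path]):
            logger.info("fit_binding: unchanged, skipping")
        else:
            curve = io.read_tsv(paths["binding"])
            fit = binding.fit_kd(curve["concentration_um"], curve["fraction_bound"])
            io.write_json(fit.as_dict(), fit_path)
            manifest.record("fit_binding", key, [fit_path])

    return out
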