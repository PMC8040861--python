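"""Orchestrate screen → fold hand-off → rank → graft → re-filter → evaluate.

Stages communicate through files in the run directory, which makes the
pipeline resumable: a stage is recomputed only when its recorded outputs
are missing or changed, or an upstream stage was recomputed.  The manifest
records a hash of the configuration, per-stage status and a checksum for
every produced file; it contains no timestamps or absolute paths, so a
rerun with the same configuration and seed produces a byte-identical
manifest.  Wall-clock timings go to the JSON-lines run log instead.

Folding is a hand-off boundary: with ``folding.mode: external`` the
pipeline ingests a directory of models produced by any folding engine;
with ``mode: simulate`` it builds a designed fragment model for the best
candidate and generates a Gaussian-noise decoy ensemble standing in for
the engine's output, which keeps the full pipeline runnable at desk scale.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, HelixgraftError
from .fixtures import (
    DEFAULT_FRAGMENT_SPAN,
    DEFAULT_LOOP_SPAN,
    make_candidate_fragment_model,
    make_decoy_ensemble,
    make_mini_barrel,
)
from .grafting import GraftSpec, extract_fragment, graft_insert
from .screening import (
    Candidate,
    InsertionSpec,
    MotifFilter,
    apply_filter,
    assemble_candidate,
    compile_motif_filter,
    generate_insert_sequences,
    rank_models_by_core_rmsd,
    select_top,
)
from .sspredict import PropensityPredictor, prediction_score
from .structure_io import SequenceRecord, read_pdb, write_fasta, write_pdb

__all__ = ["PipelineConfig", "RunManifest", "load_config", "validate_config", "run_pipeline"]

STAGES = ("setup", "screen", "fold", "rank", "graft", "refilter", "evaluate")

DEFAULT_CONFIG = {
    "seed": 1,
    "output_dir": "helixgraft_run",
    "scaffold": "builtin:mini_barrel",
    "n_sequences": 2000,
    "top_candidates": 30,
    "top_models": 12,
    "insertion_spec": {
        "fragment_span": list(DEFAULT_FRAGMENT_SPAN),
        "loop_span": list(DEFAULT_LOOP_SPAN),
        "insert_len_min": 8,
        "insert_len_max": 19,
    },
    "motif_filter": {"helix_min": 4, "helix_max": 8, "flank_min": 2, "flank_max": 3},
    "predictor": {"method": "propensity", "window": 7},
    "folding": {"mode": "simulate", "n_decoys": 50,
                "noise_sigma_min": 0.05, "noise_sigma_max": 1.0,
                "models_dir": None},
    "graft": {"anchor_rmsd_threshold": 2.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    raw: dict

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def insertion_spec(self) -> InsertionSpec:
        s = self.raw["insertion_spec"]
        return InsertionSpec(
            scaffold_id=str(self.raw["scaffold"]),
            fragment_span=tuple(s["fragment_span"]),
            loop_span=tuple(s["loop_span"]),
            insert_len_min=int(s["insert_len_min"]),
            insert_len_max=int(s["insert_len_max"]),
            alphabet=s.get("alphabet", InsertionSpec.alphabet),
        )

    def motif_filter(self) -> MotifFilter:
        return MotifFilter(**self.raw["motif_filter"])

    def predictor(self) -> PropensityPredictor:
        p = self.raw["predictor"]
        if p.get("method", "propensity") != "propensity":
            raise ConfigError(f"unknown predictor method {p.get('method')!r}")
        return PropensityPredictor(window=int(p.get("window", 7)))

    def config_hash(self) -> str:
        hashable = {k: v for k, v in self.raw.items() if k != "output_dir"}
        blob = json.dumps(hashable, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path_or_dict) -> PipelineConfig:
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"cannot parse {path_or_dict}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path_or_dict}: top level must be a mapping")
    return PipelineConfig(_merge(DEFAULT_CONFIG, raw))


def validate_config(path_or_dict) -> list[str]:
    """Return a list of problems; empty iff the configuration is runnable."""
    problems: list[str] = []
    try:
        cfg = load_config(path_or_dict)
    except ConfigError as exc:
        return [str(exc)]
    raw = cfg.raw
    if "seed" not in raw or raw["seed"] is None:
        problems.append("seed: required (no silent entropy)")
    try:
        spec = cfg.insertion_spec()
        if spec.insert_len_min > spec.insert_len_max:
            problems.append("insertion_spec.insert_len_min > insertion_spec.insert_len_max")
    except ConfigError as exc:
        problems.append(f"insertion_spec: {exc}")
    try:
        cfg.motif_filter()
    except (ConfigError, TypeError) as exc:
        problems.append(f"motif_filter: {exc}")
    w = raw.get("predictor", {}).get("window", 7)
    if not (isinstance(w, int) and w >= 1 and w % 2 == 1):
        problems.append("predictor.window: must be a positive odd integer")
    scaffold = str(raw.get("scaffold", ""))
    if not scaffold.startswith("builtin:") and not Path(scaffold).exists():
        problems.append(f"scaffold: file not found: {scaffold}")
    folding = raw.get("folding", {})
    if folding.get("mode") not in ("simulate", "external"):
        problems.append("folding.mode: must be 'simulate' or 'external'")
    if folding.get("mode") == "external":
        md = folding.get("models_dir")
        if not md or not Path(md).is_dir():
            problems.append(f"folding.models_dir: directory not found: {md}")
    for key in ("n_sequences", "top_candidates", "top_models"):
        v = raw.get(key)
        if not (isinstance(v, int) and v >= 0):
            problems.append(f"{key}: must be a non-negative integer")
    return problems


@dataclass
class RunManifest:
    config_hash: str
    stages: dict  # stage -> {"status": str, "outputs": {relpath: sha256}}
    versions: dict

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "stages": self.stages,
                "versions": self.versions}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config_hash"], d["stages"], d["versions"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksum_outputs(root: Path, paths: list[Path]) -> dict[str, str]:
    return {str(p.relative_to(root)): _sha256(p) for p in sorted(paths)}


class _Run:
    """One pipeline execution over a run directory."""

    def __init__(self, config: PipelineConfig, resume: bool = True):
        self.cfg = config
        self.root = config.output_dir
        self.resume = resume
        self.spec = config.insertion_spec()
        self.filter = config.motif_filter()
        self.predictor = config.predictor()
        self.log_path = self.root / "run.log.jsonl"
        self.previous: RunManifest | None = None
        self.stages: dict[str, dict] = {}
        self._dirty = False  # once a stage recomputes, descendants recompute

    # -- infrastructure ----------------------------------------------------
    def _log(self, **event):
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(event, sort_keys=True) + "\n")

    def _cached(self, stage: str) -> bool:
        if not self.resume or self._dirty or self.previous is None:
            return False
        if self.previous.config_hash != self.cfg.config_hash():
            return False
        rec = self.previous.stages.get(stage)
        if not rec or rec["status"] not in ("completed", "cached"):
            return False
        for rel, digest in rec["outputs"].items():
            p = self.root / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def _run_stage(self, stage: str, fn) -> None:
        if self._cached(stage):
            rec = dict(self.previous.stages[stage])
            rec["status"] = "cached"
            self.stages[stage] = rec
            self._log(stage=stage, status="cached")
            return
        self._dirty = True
        t0 = time.monotonic()
        try:
            outputs = fn()
        except Exception as exc:
            self.stages[stage] = {"status": "failed", "outputs": {}, "error": str(exc)}
            self._log(stage=stage, status="failed", error=str(exc),
                      wall_clock_s=round(time.monotonic() - t0, 3))
            raise
        self.stages[stage] = {"status": "completed",
                              "outputs": _checksum_outputs(self.root, outputs)}
        self._log(stage=stage, status="completed",
                  wall_clock_s=round(time.monotonic() - t0, 3),
                  seed=self.cfg.seed)

    # -- stages --------------------------------------------------------------
    def stage_setup(self) -> list[Path]:
        d = self.root / "setup"
        d.mkdir(parents=True, exist_ok=True)
        scaffold_name = str(self.cfg.raw["scaffold"])
        if scaffold_name == "builtin:mini_barrel":
            scaffold = make_mini_barrel()
        elif scaffold_name.startswith("builtin:"):
            raise ConfigError(f"unknown builtin scaffold {scaffold_name!r}")
        else:
            scaffold = read_pdb(scaffold_name)
        write_pdb(scaffold, d / "scaffold.pdb")
        fragment = extract_fragment(scaffold, self.spec.fragment_span)
        write_pdb(fragment, d / "fragment.pdb")
        return [d / "scaffold.pdb", d / "fragment.pdb"]

    def _scaffold(self):
        return read_pdb(self.root / "setup" / "scaffold.pdb")

    def stage_screen(self) -> list[Path]:
        d = self.root / "screen"
        d.mkdir(parents=True, exist_ok=True)
        scaffold = self._scaffold()
        chain = scaffold.first_chain_id()
        f0, f1 = self.spec.fragment_span
        fragment_seq = "".join(
            r.one_letter for r in scaffold.chains[chain] if f0 <= r.seq_id <= f1)
        inserts = generate_insert_sequences(self.spec, int(self.cfg.raw["n_sequences"]),
                                            self.cfg.seed)
        width = len(str(max(len(inserts) - 1, 1)))
        candidates = [
            assemble_candidate(fragment_seq, self.spec.loop_local_span, ins,
                               candidate_id=f"cand_{i:0{width}d}")
            for i, ins in enumerate(inserts)
        ]
        matcher = compile_motif_filter(self.filter)
        apply_filter(candidates, matcher, self.predictor)
        passed = [c for c in candidates if c.passed_filter]
        top = select_top(passed, int(self.cfg.raw["top_candidates"]))
        if not top:
            raise HelixgraftError("no candidate passed the motif filter")

        def table(cands):
            return pd.DataFrame({
                "id": [c.id for c in cands],
                "insert_seq": [c.insert_seq for c in cands],
                "assembled_seq": [c.assembled_seq for c in cands],
                "insert_start": [c.insert_region[0] for c in cands],
                "insert_end": [c.insert_region[1] for c in cands],
                "score": [round(c.score, 6) for c in cands],
                "passed": [bool(c.passed_filter) for c in cands],
            })

        table(candidates).to_csv(d / "candidates.tsv", sep="\t", index=False)
        table(top).to_csv(d / "top_candidates.tsv", sep="\t", index=False)
        write_fasta([SequenceRecord(c.id, c.assembled_seq) for c in top],
                    d / "top_candidates.fasta")
        return [d / "candidates.tsv", d / "top_candidates.tsv", d / "top_candidates.fasta"]

    def stage_fold(self) -> list[Path]:
        d = self.root / "models"
        d.mkdir(parents=True, exist_ok=True)
        folding = self.cfg.raw["folding"]
        top = pd.read_csv(self.root / "screen" / "top_candidates.tsv", sep="\t")
        best = top.iloc[0]
        insert_seq = str(best["insert_seq"])
        l0, l1 = self.spec.loop_span
        shift = len(insert_seq) - (l1 - l0 + 1)
        info = {
            "candidate_id": str(best["id"]),
            "insert_seq": insert_seq,
            "insert_span_fragment": [l0, l0 + len(insert_seq) - 1],
            "suffix_shift": shift,
            "mode": folding["mode"],
        }
        outputs = []
        if folding["mode"] == "simulate":
            scaffold = self._scaffold()
            model = make_candidate_fragment_model(
                scaffold, insert_seq, self.spec.fragment_span, self.spec.loop_span)
            n = int(folding["n_decoys"])
            sigmas = np.linspace(float(folding["noise_sigma_min"]),
                                 float(folding["noise_sigma_max"]), n)
            decoys = make_decoy_ensemble(model, n, sigmas, seed=self.cfg.seed)
            info["sigmas"] = [round(s, 6) for _, s in decoys]
            for i, (st, _sigma) in enumerate(decoys):
                p = d / f"decoy_{i:04d}.pdb"
                write_pdb(st, p)
                outputs.append(p)
        else:
            info["models_dir"] = str(folding["models_dir"])
        info_path = d / "info.json"
        with open(info_path, "w") as fh:
            json.dump(info, fh, indent=2, sort_keys=True)
        outputs.append(info_path)
        return outputs

    def _model_paths(self) -> list[Path]:
        folding = self.cfg.raw["folding"]
        if folding["mode"] == "simulate":
            return sorted((self.root / "models").glob("decoy_*.pdb"))
        return sorted(Path(folding["models_dir"]).glob("*.pdb"))

    def _core_pairs(self, shift: int) -> list[tuple[int, int]]:
        f0, f1 = self.spec.fragment_span
        l0, l1 = self.spec.loop_span
        pairs = [(i, i) for i in range(f0, l0)]
        pairs += [(i + shift, i) for i in range(l1 + 1, f1 + 1)]
        return pairs

    def stage_rank(self) -> list[Path]:
        d = self.root / "rank"
        d.mkdir(parents=True, exist_ok=True)
        with open(self.root / "models" / "info.json") as fh:
            info = json.load(fh)
        scaffold = self._scaffold()
        pairs = self._core_pairs(int(info["suffix_shift"]))
        ranking = rank_models_by_core_rmsd(
            [str(p) for p in self._model_paths()], scaffold, pairs,
            k=int(self.cfg.raw["top_models"]))
        df = pd.DataFrame(
            {"model": [Path(m).name for m, _ in ranking],
             "core_rmsd": [round(r, 6) for _, r in ranking]})
        df.to_csv(d / "ranking.tsv", sep="\t", index=False)
        return [d / "ranking.tsv"]

    def stage_graft(self) -> list[Path]:
        d = self.root / "graft"
        d.mkdir(parents=True, exist_ok=True)
        with open(self.root / "models" / "info.json") as fh:
            info = json.load(fh)
        ranking = pd.read_csv(self.root / "rank" / "ranking.tsv", sep="\t")
        best_model = read_pdb(self.root / "models" / ranking.iloc[0]["model"]) \
            if info["mode"] == "simulate" else \
            read_pdb(Path(self.cfg.raw["folding"]["models_dir"]) / ranking.iloc[0]["model"])
        scaffold = self._scaffold()
        pairs = self._core_pairs(int(info["suffix_shift"]))
        spec = GraftSpec(
            anchor_residues_fragment=[a for a, _ in pairs],
            anchor_residues_barrel=[b for _, b in pairs],
            insert_span_fragment=tuple(info["insert_span_fragment"]),
            replace_span_barrel=self.spec.loop_span,
            anchor_rmsd_threshold=float(self.cfg.raw["graft"]["anchor_rmsd_threshold"]),
        )
        result = graft_insert(scaffold, best_model, spec)
        write_pdb(result.model, d / "grafted.pdb")
        result.write_report(d / "report.json")
        return [d / "grafted.pdb", d / "report.json"]

    def stage_refilter(self) -> list[Path]:
        d = self.root / "refilter"
        d.mkdir(parents=True, exist_ok=True)
        with open(self.root / "models" / "info.json") as fh:
            info = json.load(fh)
        grafted = read_pdb(self.root / "graft" / "grafted.pdb")
        chain = grafted.first_chain_id()
        seq = grafted.chain_sequence(chain)
        first = grafted.chains[chain][0].seq_id
        l0 = self.spec.loop_span[0]
        L = len(info["insert_seq"])
        region = (l0 - first, l0 - first + L - 1)  # insert, 0-based in full seq
        pred = self.predictor(seq)
        matcher = compile_motif_filter(self.filter)
        pad = self.filter.flank_max
        window = (max(0, region[0] - pad), min(len(seq) - 1, region[1] + pad))
        out = {
            "sequence_length": len(seq),
            "insert_region": list(region),
            "passed": bool(matcher.matches(pred.labels, scope=window)),
            "score": round(prediction_score(pred, region), 6),
            "labels_insert_window": pred.labels[window[0]:window[1] + 1],
        }
        with open(d / "refilter.json", "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
        return [d / "refilter.json"]

    def stage_evaluate(self) -> list[Path]:
        from .evaluation import compare_model_to_structure

        d = self.root / "evaluate"
        d.mkdir(parents=True, exist_ok=True)
        with open(self.root / "models" / "info.json") as fh:
            info = json.load(fh)
        grafted = read_pdb(self.root / "graft" / "grafted.pdb")
        scaffold = self._scaffold()
        chain = scaffold.first_chain_id()
        l0, l1 = self.spec.loop_span
        L = len(info["insert_seq"])
        shift = int(info["suffix_shift"])
        last = scaffold.chains[chain][-1].seq_id
        mapping = [[i, i] for i in range(scaffold.chains[chain][0].seq_id, l0)]
        mapping += [[i + shift, i] for i in range(l1 + 1, last + 1)]
        f0, f1 = self.spec.fragment_span
        config = {
            "mapping": mapping,
            "regions": {"fragment_core": f"resi {f0}-{l0 - 1},{l1 + 1 + shift}-{f1 + shift}"},
            "helix_region": [l0, l0 + L - 1],
            "bfactor_regions": {"fragment": f"resi {f0}-{f1}"},
        }
        report = compare_model_to_structure(grafted, scaffold, config)
        report.to_json(d / "comparison.json")
        (d / "comparison.txt").write_text(report.summary_table() + "\n")
        return [d / "comparison.json", d / "comparison.txt"]

    # -- driver --------------------------------------------------------------
    def run(self) -> RunManifest:
        self.root.mkdir(parents=True, exist_ok=True)
        manifest_path = self.root / "manifest.json"
        if manifest_path.exists():
            try:
                self.previous = RunManifest.read(manifest_path)
            except (json.JSONDecodeError, KeyError):
                self.previous = None
        fns = {
            "setup": self.stage_setup,
            "screen": self.stage_screen,
            "fold": self.stage_fold,
            "rank": self.stage_rank,
            "graft": self.stage_graft,
            "refilter": self.stage_refilter,
            "evaluate": self.stage_evaluate,
        }
        failed = False
        for stage in STAGES:
            if failed:
                self.stages[stage] = {"status": "skipped", "outputs": {}}
                continue
            try:
                self._run_stage(stage, fns[stage])
            except Exception:
                failed = True
        manifest = RunManifest(
            config_hash=self.cfg.config_hash(),
            stages=self.stages,
            versions=_tool_versions(),
        )
        manifest.write(manifest_path)
        if failed:
            bad = [s for s, rec in self.stages.items() if rec["status"] == "failed"]
            raise HelixgraftError(f"pipeline failed at stage(s) {bad}; see manifest")
        return manifest


def _tool_versions() -> dict:
    import gemmi

    return {"helixgraft": __version__, "numpy": np.__version__,
            "gemmi": gemmi.__version__, "pandas": pd.__version__}


def run_pipeline(config, resume: bool = True) -> RunManifest:
    """Run the full pipeline from a config path, dict or PipelineConfig."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    problems = validate_config(config.raw)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return _Run(config, resume=resume).run()
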