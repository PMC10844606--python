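"""End-to-end orchestration: data → QC → matrices → fits → SNP selection → OCS.

One config document drives the whole run.  Stages execute in dependency
order, each writes its outputs under the run directory, and a manifest
records per-stage status so an interrupted or re-run invocation skips
completed stages (outputs are byte-identical under a fixed seed).

Config schema (YAML or JSON)::

    seed: 1
    out: runs/demo
    simulate:            # either this block or explicit input paths
      n_families: 25
      offspring_per_family_per_site: 10
      ...                # any SimConfig field
    # pedigree: path.csv / genotypes: path.tsv / phenotypes: path.csv
    traits: [HT, DBH, WD]
    qc: {diag_low: 0.6, within_family_low: 0.1, cluster_min: 0.15}
    models: [ABLUP, GBLUP-A, GBLUP-ALL, GBLUP-GWAS]
    snp_selection: {strategy: gwas_effect, steps: 8, top_k: 1000}
    ocs: {n_max: 30, delta_f_limit: 0.25, objective: [HT, DBH],
          constrain: [[WD, ">=", 0.0]]}
    top_n_gain: 30
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import relmat, selection, sim, snp_select
from .io import ValidationError
from .mixed_models import ModelSpec, adjust_stage1, fit_reml, predict_blup

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

KNOWN_MODELS = ("ABLUP", "GBLUP-A", "GBLUP-ADE", "GBLUP-ALL", "GBLUP-GWAS")


@dataclasses.dataclass
class PipelineConfig:
    out: str
    traits: list[str]
    seed: int = 0
    simulate: dict | None = None
    pedigree: str | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    qc: dict = dataclasses.field(default_factory=dict)
    models: list[str] = dataclasses.field(default_factory=lambda: ["ABLUP", "GBLUP-A"])
    snp_selection: dict | None = None
    ocs: dict | None = None
    top_n_gain: int = 30
    blend_weight: float = 0.01
    reml: dict = dataclasses.field(default_factory=lambda: {"tol": 1e-6, "max_iter": 300})
    stage1_genetic_term: bool = True

    def validate(self) -> None:
        unknown = [m for m in self.models if m not in KNOWN_MODELS]
        if unknown:
            raise ValidationError(f"unknown models {unknown}; choose from {KNOWN_MODELS}")
        if not self.models:
            raise ValidationError("at least one model must be requested")
        if "GBLUP-GWAS" in self.models and not self.snp_selection:
            raise ValidationError(
                "model GBLUP-GWAS requires an 'snp_selection' block (strategy/top_k)"
            )
        if self.simulate is None and not (
            self.pedigree and self.genotypes and self.phenotypes
        ):
            raise ValidationError(
                "either a 'simulate' block or pedigree+genotypes+phenotypes paths"
            )
        if self.simulate is None:
            for p in (self.pedigree, self.genotypes, self.phenotypes):
                if not Path(p).exists():
                    raise ValidationError(f"input file not found: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - fields
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc)


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = dataclasses.field(default_factory=dict)  # name -> {status, outputs}

    def path(self, outdir: Path) -> Path:
        return outdir / "manifest.json"

    def save(self, outdir: Path) -> None:
        with open(self.path(outdir), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, outdir: Path):
        p = outdir / "manifest.json"
        if not p.exists():
            return None
        with open(p) as fh:
            d = json.load(fh)
        return cls(d["config_hash"], d["version"], d["stages"])

    def done(self, stage: str) -> bool:
        info = self.stages.get(stage)
        return bool(info) and info["status"] == "ok" and all(
            Path(p).exists() for p in info["outputs"].values()
        )


def _config_hash(config: PipelineConfig) -> str:
    doc = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all requested stages; returns the manifest (also written to disk).

    Any stage failure is recorded in the manifest, downstream stages are
    skipped, and the error re-raised.
    """
    from . import __version__

    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    manifest = RunManifest.load(outdir)
    if manifest is None or manifest.config_hash != chash:
        manifest = RunManifest(chash, __version__)
    manifest.save(outdir)

    state: dict = {}
    stages = [
        ("data", _stage_data),
        ("qc", _stage_qc),
        ("matrices", _stage_matrices),
        ("adjust", _stage_adjust),
        ("fits", _stage_fits),
        ("summaries", _stage_summaries),
    ]
    if config.ocs:
        stages.append(("ocs", _stage_ocs))
    for name, fn in stages:
        if manifest.done(name) and name in ("data",):
            # cheap stages re-load their outputs; expensive ones recompute
            # in-memory state from them
            pass
        try:
            outputs = fn(config, outdir, state, manifest)
            manifest.stages[name] = {"status": "ok", "outputs": outputs}
            manifest.save(outdir)
        except Exception as e:
            manifest.stages[name] = {"status": "failed", "outputs": {}, "error": str(e)}
            manifest.save(outdir)
            log.error("stage %s failed: %s", name, e)
            raise
    return manifest


def _stage_data(config, outdir, state, manifest):
    if config.simulate is not None:
        sim_cfg = sim.SimConfig(**{**config.simulate, "seed": config.seed})
        if sorted(sim_cfg.traits) != sorted(config.traits):
            sim_cfg.target_h2 = {
                t: sim_cfg.target_h2.get(t, 0.4) for t in config.traits
            }
        datadir = outdir / "data"
        if manifest.done("data"):
            paths = manifest.stages["data"]["outputs"]
        else:
            ds = sim.simulate_dataset(sim_cfg)
            paths = sim.write_dataset(ds, datadir)
        state["pedigree"] = _io.read_pedigree(paths["pedigree"])
        state["genotypes"] = _io.read_genotypes(paths["genotypes"])
        state["phenotypes"] = _io.read_phenotypes(paths["phenotypes"], config.traits)
        return paths
    state["pedigree"] = _io.read_pedigree(config.pedigree)
    state["genotypes"] = _io.read_genotypes(config.genotypes)
    state["phenotypes"] = _io.read_phenotypes(config.phenotypes, config.traits)
    return {
        "pedigree": config.pedigree,
        "genotypes": config.genotypes,
        "phenotypes": config.phenotypes,
    }


def _stage_qc(config, outdir, state, manifest):
    geno = relmat.impute_and_freq(state["genotypes"])
    G = relmat.build_G(geno)
    report = relmat.verify_pedigree(G, state["pedigree"], **config.qc)
    out = outdir / "qc_report.json"
    with open(out, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    keep = [i for i in geno.ids if i not in set(report.removed_low_diagonal)]
    if len(keep) < geno.n:
        geno = geno.subset_individuals(keep)
        G = relmat.build_G(geno)
    # apply reassignments to the working pedigree
    if report.reassigned:
        moves = {i: new for i, _, new in report.reassigned}
        rows = [
            (i, moves.get(i, d) if d is not None else d, s)
            for i, d, s in zip(
                state["pedigree"].ids, state["pedigree"].dam, state["pedigree"].sire
            )
        ]
        state["pedigree"] = _io.PedigreeTable.from_records(rows)
    state["genotypes_imputed"] = geno
    state["G"] = G
    state["qc_report"] = report
    return {"qc_report": str(out)}


def _stage_matrices(config, outdir, state, manifest):
    outputs = {}
    A = relmat.build_A(state["pedigree"])
    state["A"] = A
    _io.write_matrix(A.ids, A.values, outdir / "A.tsv")
    outputs["A"] = str(outdir / "A.tsv")
    _io.write_matrix(state["G"].ids, state["G"].values, outdir / "G.tsv")
    outputs["G"] = str(outdir / "G.tsv")
    if "GBLUP-ADE" in config.models:
        D = relmat.build_D(state["genotypes_imputed"])
        state["D"] = D
        state["EPI"] = relmat.build_epistatic(state["G"], D)
        _io.write_matrix(D.ids, D.values, outdir / "D.tsv")
        _io.write_matrix(state["EPI"].ids, state["EPI"].values, outdir / "EPI.tsv")
        outputs["D"] = str(outdir / "D.tsv")
        outputs["EPI"] = str(outdir / "EPI.tsv")
    return outputs


def _stage_adjust(config, outdir, state, manifest):
    adjusted = adjust_stage1(
        state["phenotypes"], state["pedigree"], genetic_term=config.stage1_genetic_term
    )
    out = outdir / "phenotypes_adjusted.csv"
    _io.write_phenotypes(adjusted, out)
    state["adjusted"] = adjusted
    return {"phenotypes_adjusted": str(out)}


def _fit_one(config, state, label, traits, terms):
    spec = ModelSpec(traits, state["adjusted"].sites, terms, label)
    vc = fit_reml(spec, state["adjusted"], **config.reml)
    bvs = predict_blup(spec, state["adjusted"], vc)
    return vc, bvs


def _stage_fits(config, outdir, state, manifest):
    Gb = relmat.blend(state["G"], config.blend_weight)
    outputs = {}
    fits = {}
    for model in config.models:
        per_trait_models = {
            "ABLUP": [("additive", state["A"])],
            "GBLUP-A": [("additive", Gb)],
            "GBLUP-ADE": None,  # handled below
        }
        if model in ("ABLUP", "GBLUP-A", "GBLUP-ADE"):
            for trait in config.traits:
                if model == "GBLUP-ADE":
                    terms = [
                        ("additive", Gb),
                        ("dominance", relmat.blend(state["D"], config.blend_weight)),
                        ("epistatic", relmat.blend(state["EPI"], config.blend_weight)),
                    ]
                else:
                    terms = per_trait_models[model]
                vc, bvs = _fit_one(config, state, model, [trait], terms)
                fits[(model, trait)] = (vc, bvs)
        elif model == "GBLUP-ALL":
            vc, bvs = _fit_one(
                config, state, model, list(config.traits), [("additive", Gb)]
            )
            fits[(model, "__multi__")] = (vc, bvs)
        elif model == "GBLUP-GWAS":
            snp_set = _gwas_snp_union(config, state, fits, outdir, outputs)
            geno_sub = state["genotypes_imputed"].subset_snps(sorted(snp_set))
            G_gwas = relmat.blend(relmat.build_G(geno_sub), config.blend_weight)
            vc, bvs = _fit_one(
                config, state, model, list(config.traits), [("additive", G_gwas)]
            )
            fits[(model, "__multi__")] = (vc, bvs)
    state["fits"] = fits
    # persist breeding values
    frames = []
    for (model, tag), (vc, bvs) in fits.items():
        frames.append(bvs.data.assign(model=model))
    bv_path = outdir / "breeding_values.tsv"
    pd.concat(frames, ignore_index=True).to_csv(bv_path, sep="\t", index=False)
    outputs["breeding_values"] = str(bv_path)
    return outputs


def _gwas_snp_union(config, state, fits, outdir, outputs):
    """Per-trait ssGWAS rankings from GBLUP-A fits; union of top-k SNPs."""
    sel = config.snp_selection or {}
    top_k = int(sel.get("top_k", max(1, state["genotypes_imputed"].m // 3)))
    Gb = relmat.blend(state["G"], config.blend_weight)
    rankings = {}
    for trait in config.traits:
        key = ("GBLUP-A", trait)
        if key in fits:
            vc, bvs = fits[key]
        else:
            vc, bvs = _fit_one(config, state, "GBLUP-A", [trait], [("additive", Gb)])
            fits[key] = (vc, bvs)
        eff = snp_select.backsolve_snp_effects(
            state["genotypes_imputed"], state["G"], bvs, trait
        )
        rankings[trait] = snp_select.rank_snps(eff, "gwas_effect")
    union = snp_select.combine_trait_top(rankings, top_k)
    path = outdir / "combined_snps.txt"
    path.write_text("\n".join(sorted(union)) + "\n")
    outputs["combined_snps"] = str(path)
    return union


def _stage_summaries(config, outdir, state, manifest):
    rows = []
    for (model, tag), (vc, bvs) in state["fits"].items():
        h2 = selection.heritability(vc, model)
        ta = selection.theoretical_accuracy(bvs, vc)
        for trait in [tag] if tag != "__multi__" else config.traits:
            mean_ta = float(ta[ta["trait"] == trait]["ta"].mean())
            tm = float(
                state["phenotypes"].data.query("trait == @trait")["value"].mean()
            )
            gain = selection.expected_gain(
                bvs, trait, min(config.top_n_gain, bvs.data["id"].nunique()), tm
            )
            rows.append(
                {
                    "model": model,
                    "trait": trait,
                    "h2": round(h2[trait][0], 4),
                    "h2_se": round(h2[trait][1], 4),
                    "mean_ta": round(mean_ta, 4),
                    f"gain_top{config.top_n_gain}_pct": round(gain, 3),
                }
            )
    path = outdir / "comparison.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    state["comparison"] = rows
    return {"comparison": str(path)}


def _stage_ocs(config, outdir, state, manifest):
    oc = dict(config.ocs)
    objective = oc.pop("objective", [config.traits[0]])
    constraints = [tuple(c) for c in oc.pop("constrain", [])]
    model = oc.pop("model", None)
    cfg = selection.OCSConfig(
        n_max=int(oc.get("n_max", 30)),
        delta_f_limit=oc.get("delta_f_limit"),
        coancestry_definition=oc.get("coancestry_definition", "mean_pairwise"),
        auxiliary_constraints=constraints,
        seed=config.seed,
    )
    fits = state["fits"]
    if model is None:
        for cand in ("GBLUP-GWAS", "GBLUP-ALL", "GBLUP-A", "ABLUP"):
            hit = [k for k in fits if k[0] == cand]
            if hit:
                model = cand
                break
    multi = [(m, t) for (m, t) in fits if m == model and t == "__multi__"]
    if multi:
        vc, bvs = fits[multi[0]]
    else:
        frames = [fits[(m, t)][1].data for (m, t) in fits if m == model]
        from .mixed_models import BreedingValueSet

        bvs = BreedingValueSet(pd.concat(frames, ignore_index=True), model)
    K = state["A"] if model == "ABLUP" else state["G"]
    sol = selection.ocs_optimize(bvs, K, cfg, list(objective))
    out = outdir / "ocs_solution.json"
    with open(out, "w") as fh:
        json.dump(
            {
                "model": model,
                "selected": sol.selected,
                "n_selected": len(sol.selected),
                "gain_standardized": sol.gain,
                "gain_raw": sol.gain_raw,
                "delta_f": sol.delta_f,
                "solver": sol.solver,
                "objective": sol.objective,
            },
            fh,
            indent=1,
        )
    return {"ocs_solution": str(out)}
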