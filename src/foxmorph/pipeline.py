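"""End-to-end orchestration of the analysis chain.

Runs the workflow in its natural order — read landmarks → adult filter →
GPA → partial warps → two-way MANOVA with canonical axes → dimorphism
bootstrap → (clade) allometry correction → species means → PCA → K.mult →
micro/macro trajectory comparison with RRPP — writing per-stage outputs, a
combined JSON report and a timestamped log.  Dorsal and ventral aspects are
independent runs.  Comparative stages are skipped with a logged notice when
no clade data or tree is supplied.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import landmark_io, synthetic
from .dimorphism import compare_dimorphism
from .phylosignal import k_mult_test
from .shape_stats import (
    allometry_regression,
    canonical_axis,
    manova_two_way,
    pca,
    species_mean_shapes,
)
from .superimpose import align_to, gpa, partial_warps
from .trajectory import compare_trajectories, habitat_canonical_scores, pc1_scores, rrpp_pairwise

logger = logging.getLogger(__name__)

ALL_ANALYSES = ("manova", "dimorphism", "allometry", "pca", "kmult", "trajectory")


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run (one aspect).

    Either file inputs (``tps`` + ``metadata``, optionally ``clade_tps`` +
    ``clade_metadata`` + ``newick``) or a synthetic specification
    (``synthetic_spec``) must be provided.  Resampling defaults follow the
    workflow this pipeline reproduces: 900 bootstraps, 1000 permutations,
    1000 null simulations.
    """

    tps: str | None = None
    metadata: str | None = None
    newick: str | None = None
    clade_tps: str | None = None
    clade_metadata: str | None = None
    synthetic_spec: "synthetic.SyntheticSpec | None" = None
    aspect: str = "dorsal"
    analyses: tuple = ALL_ANALYSES
    n_boot: int = 900
    n_perm: int = 1000
    n_sim: int = 1000
    seed: int = 0
    outdir: str = "results/run"

    def validate(self) -> None:
        if self.synthetic_spec is None and self.tps is None:
            raise ValueError("provide either input files or a synthetic spec")
        for count, name in ((self.n_boot, "n_boot"), (self.n_perm, "n_perm"), (self.n_sim, "n_sim")):
            if count < 1:
                raise ValueError(f"{name} must be ≥ 1")
        for path in (self.tps, self.metadata, self.newick, self.clade_tps, self.clade_metadata):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


class _StageLog:
    def __init__(self, outdir: Path):
        self.text_path = outdir / "pipeline.log"
        self.jsonl_path = outdir / "events.jsonl"
        self.text = open(self.text_path, "a")
        self.jsonl = open(self.jsonl_path, "a")

    def event(self, stage: str, status: str, **extra):
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.text.write(f"{stamp} [{stage}] {status} {extra if extra else ''}\n")
        self.jsonl.write(json.dumps({"stage": stage, "status": status, **extra}) + "\n")
        self.text.flush()
        self.jsonl.flush()

    def close(self):
        self.text.close()
        self.jsonl.close()


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _coords_csv(path: Path, ids, coords) -> None:
    flat = np.asarray(coords).reshape(len(ids), -1)
    cols = []
    for j in range(flat.shape[1] // 2):
        cols += [f"x{j + 1}", f"y{j + 1}"]
    pd.DataFrame(flat, index=pd.Index(ids, name="specimen_id"), columns=cols).to_csv(path)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the combined report dict.

    Stage failures abort with the stage name and cause; outputs written
    before the failure are preserved.  Inputs are never mutated.  Two runs
    with the same config and seed produce byte-identical reports.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _StageLog(outdir)
    report: dict = {"aspect": cfg.aspect, "seed": cfg.seed,
                    "n_boot": cfg.n_boot, "n_perm": cfg.n_perm, "n_sim": cfg.n_sim}
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    seed_of = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
               zip(["dimorphism", "allometry", "kmult", "trajectory", "rrpp", "misc"], seeds)}
    report["stage_seeds"] = seed_of

    stage = "load"
    try:
        phy = None
        clade_ds = None
        if cfg.synthetic_spec is not None:
            spec = cfg.synthetic_spec
            ds, truth = synthetic.generate_population(spec)
            out = synthetic.generate_clade(spec, individuals=True)
            clade_labels, clade_means, phy, clade_truth, clade_ds = out
            report["inputs"] = {"mode": "synthetic", "seed": spec.seed,
                                "n": ds.n, "k": ds.k, "n_clade": clade_ds.n}
        else:
            ds = landmark_io.read_tps(cfg.tps, aspect=cfg.aspect)
            if cfg.metadata:
                ds = landmark_io.attach_metadata(ds, cfg.metadata)
            if cfg.clade_tps:
                clade_ds = landmark_io.read_tps(cfg.clade_tps, aspect=cfg.aspect)
                if cfg.clade_metadata:
                    clade_ds = landmark_io.attach_metadata(clade_ds, cfg.clade_metadata)
            if cfg.newick:
                phy = landmark_io.read_newick(cfg.newick)
            report["inputs"] = {"mode": "files", "tps": cfg.tps, "n": ds.n, "k": ds.k}
        log.event(stage, "ok", n=ds.n, k=ds.k)

        stage = "adult_filter"
        if all("adult" in c.metadata for c in ds.configurations):
            before = ds.n
            ds = landmark_io.filter_adults(ds)
            log.event(stage, "ok", kept=ds.n, dropped=before - ds.n)
        else:
            log.event(stage, "skipped", reason="no adult flags")

        stage = "gpa"
        space = gpa(ds)
        _coords_csv(outdir / "aligned.csv", space.ids, space.aligned)
        pd.DataFrame(
            {"specimen_id": space.ids, "centroid_size": space.centroid_sizes}
        ).to_csv(outdir / "centroid_sizes.csv", index=False)
        log.event(stage, "ok", n=space.n)

        stage = "partial_warps"
        warps = partial_warps(space)
        pd.DataFrame(
            warps.scores,
            index=pd.Index(space.ids, name="specimen_id"),
            columns=[f"pw{j + 1}" for j in range(warps.p)],
        ).to_csv(outdir / "partial_warp_scores.csv")
        log.event(stage, "ok", p=warps.p)

        habitat = space.meta_column("habitat")
        sex = space.meta_column("sex")

        if "manova" in cfg.analyses:
            stage = "manova"
            res = manova_two_way(warps.scores, habitat, sex)
            report["manova"] = res.to_dict()
            _write_json(outdir / "manova.json", res.to_dict())
            (outdir / "manova_table.txt").write_text(res.table() + "\n")
            axes = {}
            for effect in ("habitat", "sex"):
                ax = canonical_axis(warps.scores, effect, habitat, sex)
                axes[effect] = {"group_means": ax.group_means}
                pd.DataFrame(
                    {"specimen_id": space.ids, "score": ax.scores}
                ).to_csv(outdir / f"canonical_{effect}.csv", index=False)
            report["canonical_axes"] = axes
            log.event(stage, "ok")

        if "dimorphism" in cfg.analyses:
            stage = "dimorphism"
            dim = compare_dimorphism(
                space, habitat, sex, n_boot=cfg.n_boot, seed=seed_of["dimorphism"]
            )
            report["dimorphism"] = dim.to_dict()
            _write_json(outdir / "dimorphism.json", dim.to_dict())
            log.event(stage, "ok", pct=dim.percent_reduction)

        # ---- comparative stages need clade data and a tree ----
        if clade_ds is None or phy is None:
            log.event("comparative", "skipped", reason="no clade data or tree supplied")
            _write_json(outdir / "report.json", report)
            return report

        stage = "clade_gpa"
        clade_space = gpa(clade_ds)
        clade_space = align_to(clade_space, space.consensus)
        log.event(stage, "ok", n=clade_space.n)

        if "allometry" in cfg.analyses:
            stage = "allometry"
            allo = allometry_regression(
                clade_space, n_perm=min(cfg.n_perm, 999), seed=seed_of["allometry"]
            )
            report["allometry"] = allo.to_dict()
            _write_json(outdir / "allometry.json", allo.to_dict())
            clade_coords = allo.residual_shapes
            log.event(stage, "ok", r2=allo.r_squared)
        else:
            clade_coords = clade_space.aligned

        stage = "species_means"
        labels, means = species_mean_shapes(
            clade_coords, clade_space.meta_column("species")
        )
        _coords_csv(outdir / "species_means.csv", labels, means)
        log.event(stage, "ok", n_species=len(labels))

        if "pca" in cfg.analyses:
            stage = "pca"
            mean_pca = pca(means.reshape(len(labels), -1))
            pd.DataFrame(
                mean_pca.scores[:, : min(6, mean_pca.scores.shape[1])],
                index=pd.Index(labels, name="species"),
            ).to_csv(outdir / "species_pc_scores.csv")
            report["pca"] = {
                "eigenvalues": [float(v) for v in mean_pca.eigenvalues[:6]],
                "pc1_percent": float(
                    100 * mean_pca.eigenvalues[0] / mean_pca.eigenvalues.sum()
                ),
            }
            log.event(stage, "ok")

        if "kmult" in cfg.analyses:
            stage = "kmult"
            tips = set(phy.tips)
            keep = [i for i, lab in enumerate(labels) if lab in tips]
            if len(keep) < len(labels):
                log.event(stage, "note", dropped=[labels[i] for i in range(len(labels)) if i not in keep])
            data = means.reshape(len(labels), -1)[keep]
            kres = k_mult_test(
                data, phy, n_sim=cfg.n_sim, seed=np.random.default_rng(seed_of["kmult"]),
                labels=[labels[i] for i in keep],
            )
            report["kmult"] = kres.to_dict()
            _write_json(outdir / "kmult.json", kres.to_dict())
            pd.DataFrame({"null_k": kres.null_distribution}).to_csv(
                outdir / "kmult_null.csv", index=False
            )
            log.event(stage, "ok", k=kres.k_mult, p=kres.p_value)

        if "trajectory" in cfg.analyses:
            stage = "trajectory"
            micro_coords = space.aligned.reshape(space.n, -1)
            macro_coords = means.reshape(len(labels), -1)
            comp = compare_trajectories(
                micro_coords, habitat, sex, macro_coords,
                n_boot=cfg.n_boot, seed=np.random.default_rng(seed_of["trajectory"]),
            )
            report["trajectory"] = comp.to_dict()
            _write_json(outdir / "trajectory.json", comp.to_dict())
            pd.DataFrame(
                {"angle": comp.boot_angles, "angle_unaligned": comp.boot_angles_unaligned}
            ).to_csv(outdir / "trajectory_boot_angles.csv", index=False)

            micro_scores = habitat_canonical_scores(micro_coords, habitat, sex)
            macro_scores = pc1_scores(macro_coords)
            stacked = np.vstack([micro_coords, macro_coords])
            groups = np.array(["micro"] * space.n + ["macro"] * len(labels))
            scores_all = np.concatenate([micro_scores, macro_scores])
            rrpp = rrpp_pairwise(
                stacked, groups, scores_all, n_perm=cfg.n_perm,
                seed=np.random.default_rng(seed_of["rrpp"]),
            )
            report["rrpp"] = rrpp.to_dict()
            _write_json(outdir / "rrpp.json", rrpp.to_dict())
            log.event(stage, "ok", theta=comp.theta_obs, verdict=comp.verdict)

        _write_json(outdir / "report.json", report)
        log.event("pipeline", "done")
        return report
    except Exception as exc:
        log.event(stage, "failed", error=str(exc))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.close()
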