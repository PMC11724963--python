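"""End-to-end orchestration of the digital-CMS study flow on one config.

``run_all`` drives: synthesise (or ingest) cohorts -> cross-cohort triplet-MIL
training -> held-out scoring -> Youden/KM/log-rank/Cox stratification ->
exemplar mining -> tumour-microenvironment profiling, writing every stage's
outputs plus a provenance manifest (config hash, package version, seed) into
one run directory.  All randomness flows from the single config seed through
per-stage substreams, so stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort_io, exemplars, survival, synthetic, tme, tripletmil

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; every tunable has a value."""

    out_dir: str = "runs/digicms"
    cohort_ids: tuple[str, ...] = ("cohortA", "cohortB", "cohortC")
    n_patients_per_class: int = 20
    patches_per_bag: tuple[int, int] = (96, 160)
    signal_fraction: float = 0.3
    effect_size: float = 2.0
    survival_hazard_ratio: float = 2.0
    censoring_rate: float = 0.3
    alpha1: float = 0.5
    alpha2: float = 0.1
    epochs: int = 20
    n_folds: int = 3
    top_k_patches: int = 20
    n_exemplar_clusters: int = 9
    min_tissue_fraction: float = 0.8
    tumour_rich_min_neoplastic: int = 50
    bh_alpha: float = 0.05
    dab_threshold: float = 0.15
    n_tme_regions_per_class: int = 40
    endpoint: str = "dss"
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort_ids" in raw:
            raw["cohort_ids"] = tuple(raw["cohort_ids"])
        if "patches_per_bag" in raw:
            raw["patches_per_bag"] = tuple(raw["patches_per_bag"])
        return RunConfig(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort_ids"] = list(d["cohort_ids"])
        d["patches_per_bag"] = list(d["patches_per_bag"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(config: RunConfig, stage: str) -> int:
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _synthesize(config: RunConfig) -> dict[str, synthetic.SyntheticCohort]:
    cohorts = {}
    for i, cid in enumerate(config.cohort_ids):
        spec = synthetic.SyntheticSpec(
            n_patients_per_class=config.n_patients_per_class,
            patches_per_bag=config.patches_per_bag,
            signal_fraction=config.signal_fraction,
            effect_size=config.effect_size,
            survival_hazard_ratio=config.survival_hazard_ratio,
            censoring_rate=config.censoring_rate,
            seed=_stage_seed(config, f"synth:{i}"),
        )
        cohorts[cid] = synthetic.generate_cohort(spec, cohort_id=cid)
    return cohorts


def run_all(config: RunConfig) -> Path:
    """Run the whole pipeline; returns the run directory.

    Re-running with an identical config and seed reproduces all outputs.
    Any stage failure propagates with the stage name prepended.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    provenance = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
    }

    def stage(name: str):
        provenance["stages"].append(name)
        return name

    try:
        stage("synthesize")
        cohorts = _synthesize(config)
        clinical = pd.concat([c.clinical for c in cohorts.values()], ignore_index=True)
        cohort_io.write_clinical_table(clinical, out / "clinical.csv")
        bags = {cid: tripletmil.bags_from_cohort(c) for cid, c in cohorts.items()}

        stage("train")
        plan = tripletmil.CVPlan.leave_one_cohort_out(
            list(config.cohort_ids), n_folds=config.n_folds,
            seed=_stage_seed(config, "cv"),
        )
        params = tripletmil.TripletLossParams(alpha1=config.alpha1, alpha2=config.alpha2)
        schedule = tripletmil.TrainSchedule(epochs=config.epochs)
        results = tripletmil.run_cross_cohort(plan, bags, params, schedule)

        stage("score")
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for r in results:
            tag = f"setting-{r.test_cohort}"
            cohort_io.write_score_table(r.score_table, out / f"scores_{tag}.csv")
            for k, s in enumerate(r.fold_scorers):
                np.savez_compressed(models_dir / f"{tag}_fold{k}.npz",
                                    W1=s.W1, b1=s.b1, W2=s.W2, b2=s.b2)
                (models_dir / f"{tag}_fold{k}.log.jsonl").write_text(
                    "\n".join(json.dumps(e) for e in s.training_log)
                )

        stage("stratify")
        strat_rows = []
        for r in results:
            roc_d = survival.roc_auc(r.discovery_scores["digital_cms_score"],
                                     r.discovery_scores["cms_label"])
            cutoff = survival.youden_cutoff(roc_d)
            table = r.score_table.merge(clinical, on="patient_id")
            table["risk_group"] = np.where(
                table["digital_cms_score"] >= cutoff, "high-risk", "low-risk"
            )
            tcol, ecol = f"{config.endpoint}_time", f"{config.endpoint}_event"
            groups = {
                g: (sub[tcol].to_numpy(), sub[ecol].to_numpy())
                for g, sub in table.groupby("risk_group")
            }
            if len(groups) == 2:
                km = survival.km_logrank(groups)
                for gname, curve in km.curves.items():
                    curve.to_csv(out / f"km_{r.test_cohort}_{gname}.csv", index=False)
                logrank_p = km.p_value
            else:
                logrank_p = float("nan")
            table["digital_cms_class"] = (table["digital_cms_score"] >= cutoff).astype(int)
            # full clinical covariate set; on small cohorts sparse categorical
            # levels can be collinear, so fall back to reduced models
            for covs in (
                ["digital_cms_class", "hpv_type", "stage", "age", "treatment"],
                ["digital_cms_class", "stage", "age"],
                ["digital_cms_class", "age"],
            ):
                try:
                    cox = survival.fit_coxph(table, tcol, ecol, covs)
                    break
                except ValueError:
                    continue
            else:
                cox = pd.DataFrame()
            cox.to_csv(out / f"cox_{r.test_cohort}.csv", index=False)
            strat_rows.append({
                "test_cohort": r.test_cohort,
                "discovery_auc": roc_d.auc,
                "test_auc": survival.roc_auc(
                    r.score_table["digital_cms_score"], r.score_table["cms_label"]
                ).auc,
                "youden_cutoff": cutoff,
                "logrank_p": logrank_p,
            })
        pd.DataFrame(strat_rows).to_csv(out / "stratification.csv", index=False)

        stage("exemplars")
        first = results[0]
        test_bags = bags[first.test_cohort]
        selected = exemplars.select_representative_patches(
            test_bags, first.best_scorer, k=config.top_k_patches
        )
        rows = []
        for group_label in (0, 1):
            feats, meta = [], []
            for pid, sel in selected.items():
                if sel.label != group_label:
                    continue
                bag = next(b for b in test_bags if b.patient_id == pid)
                feats.append(bag.features[sel.indices])
                meta.extend(
                    (pid, int(i), float(s)) for i, s in zip(sel.indices, sel.scores)
                )
            X = np.concatenate(feats, axis=0)
            labels_, medoids = exemplars.cluster_exemplars(
                X, n_clusters=config.n_exemplar_clusters,
                seed=_stage_seed(config, f"kmeans:{group_label}"),
            )
            for (pid, idx, score), cl in zip(meta, labels_):
                rows.append({"group": f"C{group_label + 1}", "cluster": int(cl),
                             "patient_id": pid, "patch_index": idx,
                             "digital_cms_score": score})
        pd.DataFrame(rows).to_csv(out / "exemplar_manifest.csv", index=False)

        stage("profile")
        rng = np.random.default_rng(_stage_seed(config, "tme"))
        spec0 = next(iter(cohorts.values())).spec
        profs: dict[int, dict[str, list[tme.RegionProfile]]] = {0: {}, 1: {}}
        for label in (0, 1):
            for vocab in ("V5", "V6"):
                profs[label][vocab] = [
                    tme.profile_region(
                        synthetic.generate_nuclei(spec0, label, vocab, rng=rng),
                        region_area_px=256 * 256, mpp=spec0.mpp,
                        vocabulary=vocab, region_id=f"C{label + 1}-{vocab}-{i}",
                    )
                    for i in range(config.n_tme_regions_per_class)
                ]
        comparisons = []
        for vocab in ("V5", "V6"):
            comp = tme.compare_groups(profs[0][vocab], profs[1][vocab],
                                      alpha=config.bh_alpha)
            comp.insert(0, "vocabulary", vocab)
            comparisons.append(comp)
        pd.concat(comparisons, ignore_index=True).to_csv(
            out / "tme_comparisons.csv", index=False
        )
    except Exception as exc:
        failed = provenance["stages"][-1] if provenance["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc
    finally:
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
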