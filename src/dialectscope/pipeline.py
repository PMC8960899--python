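"""End-to-end orchestration: scenario -> songs -> classification/similarity
-> tracking -> networks -> pairs -> hypothesis fits, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dialect_classifier as dc, hypothesis_models as hm
from . import motif_similarity as ms
from . import pairing_analysis as pa
from . import social_tracking as st
from .synthetic_data import (
    Scenario,
    ScenarioConfig,
    make_replicate,
    render_motif_audio,
    render_recordings,
    simulate_interactions,
    simulate_tracking,
)
from .synthetic_data.io import write_birds_csv, write_fixes_csv

log = logging.getLogger("dialectscope")

STAGES = ("generate", "songs", "classify", "similarity", "tracking", "pairing", "hypotheses")


@dataclass
class RunConfig:
    scenario: ScenarioConfig
    master_seed: int = 0
    out_dir: Path = Path("runs/r1")
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    preset: str = "desk"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.preset == "full":
            self.scenario.day_length = 14.5


@dataclass
class RunManifest:
    config_hash: str
    stage_seeds: dict[str, int]
    checksums: dict[str, str]
    version: str = __version__


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed: hash(master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(results: dict, key: str, needed_by: str):
    if key not in results:
        raise RuntimeError(
            f"stage {needed_by!r} requires output {key!r}; enable its upstream stage"
        )
    return results[key]


def run_pipeline(config: RunConfig) -> tuple[RunManifest, dict]:
    """Execute enabled stages in dependency order; returns (manifest, results).

    Results hold in-memory stage outputs; CSV/JSON artefacts and a markdown
    report are written under ``config.out_dir``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.master_seed, s) for s in STAGES}
    results: dict = {}
    files: list[Path] = []

    if config.stages.get("generate", True):
        sc = make_replicate(config.scenario, seed=seeds["generate"])
        results["scenario"] = sc
        write_birds_csv([p.bird for p in sc.gen1 + sc.gen2 + sc.extra_peers], out / "birds.csv")
        pd.DataFrame(sc.true_pairs, columns=["female_id", "male_id"]).to_csv(
            out / "true_pairs.csv", index=False
        )
        files += [out / "birds.csv", out / "true_pairs.csv"]
        log.info("generated scenario: %d gen-1, %d gen-2 birds", len(sc.gen1), len(sc.gen2))

    if config.stages.get("songs", True):
        sc: Scenario = _require(results, "scenario", "songs")
        results["train_recs"] = render_recordings(sc.gen1, 2, seeds["songs"])
        results["test_recs"] = render_recordings(sc.gen2, 2, seeds["songs"] + 1)
        results["peer_recs"] = render_recordings(sc.extra_peers, 2, seeds["songs"] + 2)
        log.info("rendered %d training and %d test recordings",
                 len(results["train_recs"]), len(results["test_recs"]))

    if config.stages.get("classify", True):
        sc = _require(results, "scenario", "classify")
        train_recs = _require(results, "train_recs", "classify")
        test_recs = _require(results, "test_recs", "classify")
        pop_of = {p.bird.bird_id: p.bird.genetic_pop for p in sc.gen1}
        pop_of.update({p.bird.bird_id: p.bird.rearing_pop for p in sc.gen2})
        train = {pid: [(b, r) for b, r in train_recs if pop_of[b] == pid] for pid in sc.populations}
        # held-out set: only males cross-fostered within population
        within = {
            p.bird.bird_id for p in sc.gen2 if p.bird.genetic_pop == p.bird.rearing_pop
        }
        test = {
            pid: [(b, r) for b, r in test_recs if b in within and pop_of[b] == pid]
            for pid in sc.populations
        }
        matrix, _ = dc.population_classification_success(train, test, seed=seeds["classify"])
        matrix.to_csv(out / "classification_matrix.csv")
        files.append(out / "classification_matrix.csv")
        results["classification_matrix"] = matrix

        # per-aviary ML similarity (parents and peers modes)
        peer_recs = _require(results, "peer_recs", "classify")
        scores = []
        other_pop = {a: b for a, b in zip(sc.populations, reversed(list(sc.populations)))}
        by_father: dict[str, list] = {}
        for b, r in train_recs:
            by_father.setdefault(b, []).append((b, r))
        by_peer: dict[str, list] = {}
        for b, r in peer_recs:
            by_peer.setdefault(b, []).append((b, r))
        males = [(b, r) for b, r in test_recs
                 if any(p.bird.bird_id == b and p.bird.sex == "M" for p in sc.gen2)]
        aviaries = sorted(sc.fathers_of_aviary)
        for aviary in aviaries:
            pop = aviary.split("-")[0]
            contrast_aviary = next(a for a in aviaries if a.split("-")[0] == other_pop[pop])
            for mode, cohort_ids, contrast_ids in (
                ("parents", sc.fathers_of_aviary[aviary], sc.fathers_of_aviary[contrast_aviary]),
                ("peers", sc.peers_of_aviary(aviary), sc.peers_of_aviary(contrast_aviary)),
            ):
                source = by_father if mode == "parents" else by_peer
                tutor = [item for bid in cohort_ids for item in source.get(bid, [])]
                contrast = [item for bid in contrast_ids for item in source.get(bid, [])]
                for s in dc.ml_similarity(aviary, tutor, contrast, males,
                                          seeds["classify"], mode=mode):
                    scores.append(
                        {"male_id": s.male_id, "female_aviary": s.female_rearing_aviary,
                         "mode": s.mode, "score": s.score}
                    )
        ml_df = pd.DataFrame(scores)
        ml_df.to_csv(out / "ml_similarity.csv", index=False)
        files.append(out / "ml_similarity.csv")
        results["ml_similarity"] = ml_df

    if config.stages.get("similarity", True):
        sc = _require(results, "scenario", "similarity")
        seed = seeds["similarity"]
        audio = {}
        for p in sc.gen1 + sc.gen2 + sc.extra_peers:
            if p.motif is not None:
                audio[p.bird.bird_id] = render_motif_audio(p.motif, seed)
        rows = []
        aviaries = sorted(sc.fathers_of_aviary)
        males = [p.bird.bird_id for p in sc.gen2 if p.bird.sex == "M"]
        for aviary in aviaries:
            cohorts = {
                "parents": [(b, audio[b]) for b in sc.fathers_of_aviary[aviary]],
                "peers": [(b, audio[b]) for b in sc.peers_of_aviary(aviary)],
            }
            for mode, cohort in cohorts.items():
                if not cohort:
                    continue
                for m in males:
                    s = ms.context_similarities(m, audio[m], cohort, mode=mode)
                    rows.append({"male_id": m, "female_aviary": aviary,
                                 "mode": mode, "score": s.value})
        sap_df = pd.DataFrame(rows)
        sap_df.to_csv(out / "sap_similarity.csv", index=False)
        files.append(out / "sap_similarity.csv")
        results["sap_similarity"] = sap_df

    if config.stages.get("tracking", True):
        sc = _require(results, "scenario", "tracking")
        fixes = simulate_tracking(
            sc.gen2_birds, sc.config.preference, sc.true_pairs, sc.design,
            seed=seeds["tracking"], pair_attraction=sc.config.pair_attraction,
        )
        write_fixes_csv(fixes, out / "fixes.csv")
        files.append(out / "fixes.csv")
        daily = st.dyad_daily_distances(fixes, sc.gen2_birds)
        daily.to_csv(out / "dyad_days.csv", index=False)
        files.append(out / "dyad_days.csv")
        period = st.aggregate_dyads(daily)
        net = st.build_network(period, sc.gen2_birds, scope="between_sex")
        assort = st.permutation_test(net, "rearing_pop", n_perm=1000, seed=seeds["tracking"])
        st.write_assortativity_report(assort, out / "assortativity.json")
        st.write_network(net, out / "network.graphml", out / "network_edges.csv")
        files += [out / "assortativity.json", out / "network_edges.csv"]
        series_r, trend_r = st.daily_assortment_series(daily, sc.gen2_birds, "rearing_pop")
        series_g, trend_g = st.daily_assortment_series(daily, sc.gen2_birds, "genetic_pop")
        results.update(
            fixes=fixes, dyad_days=daily, period_dyads=period, network=net,
            assortativity=assort,
            daily_series={"rearing_pop": (series_r, trend_r), "genetic_pop": (series_g, trend_g)},
        )

    if config.stages.get("pairing", True):
        sc = _require(results, "scenario", "pairing")
        counts = simulate_interactions(
            sc.gen2_birds, sc.true_pairs, sc.config.background_lambda,
            sc.config.bonded_lambda, seed=seeds["pairing"],
        )
        counts.drop(columns=["bonded"]).to_csv(out / "interactions.csv", index=False)
        files.append(out / "interactions.csv")
        fit = pa.fit_ztp(counts["count"].to_numpy())
        cutoff = pa.choose_cutoff(counts["count"].to_numpy(), fit, override=5)
        pairs = pa.call_pairs(counts, cutoff, all_birds=[b.bird_id for b in sc.gen2_birds])
        pd.DataFrame(pairs.pairs, columns=["female_id", "male_id", "count"]).to_csv(
            out / "pairs.csv", index=False
        )
        files.append(out / "pairs.csv")
        attr = {b.bird_id: b.rearing_pop for b in sc.gen2_birds}
        summary = pa.assortment_test(pairs, attr, attribute="rearing_pop")
        (out / "pairing_summary.json").write_text(
            json.dumps(
                {"cutoff": pairs.cutoff_used, "n_pairs": summary.n_pairs,
                 "proportion_assortative": summary.proportion,
                 "percentage": summary.percentage_rounded,
                 "binomial_p": summary.binomial_p_two_tailed}, indent=2)
        )
        files.append(out / "pairing_summary.json")
        results.update(interaction_counts=counts, ztp_fit=fit, pair_bonds=pairs,
                       assortment=summary)

    if config.stages.get("hypotheses", True):
        sc = _require(results, "scenario", "hypotheses")
        pairs = _require(results, "pair_bonds", "hypotheses")
        obs = hm.observed_matrix(pairs.as_tuples(), sc.gen2_birds)
        obs.to_frame().to_csv(out / "observed_matrix.csv")
        files.append(out / "observed_matrix.csv")
        composition = {
            sex: {
                t: sum(1 for b in sc.gen2_birds if b.sex == sex and b.lineage_code[:2] == t)
                for t in hm.PAIR_TYPES
            }
            for sex in ("F", "M")
        }
        hyps = [hm.hypothesis(n) for n in ("H1", "H2", "H3")]
        corr = {}
        for h in hyps:
            e = hm.expected_matrix(h, composition, obs.total)
            r, p = hm.matrix_correlation(e, obs)
            corr[h.name] = {"r": r, "p": p}
        mixture = hm.fit_mixture(obs, hyps, composition, grid_step=0.05)
        results.update(observed_matrix=obs, hypothesis_correlations=corr, mixture=mixture)

        model_fit = None
        if "ml_similarity" in results and "sap_similarity" in results and "dyad_days" in results:
            ml = results["ml_similarity"]
            sap = results["sap_similarity"]
            ml_peers = {
                (r.male_id, r.female_aviary): r.score
                for r in ml[ml["mode"] == "peers"].itertuples()
            }
            sap_peers = {
                (r.male_id, r.female_aviary): r.score
                for r in sap[sap["mode"] == "peers"].itertuples()
            }
            females = [b.bird_id for b in sc.gen2_birds if b.sex == "F"]
            males = [b.bird_id for b in sc.gen2_birds if b.sex == "M"]
            dyads = [(f, m) for f in females for m in males]
            pred = hm.dyad_predictors(dyads, sc.gen2_birds, ml_peers, sap_peers)
            model_fit = hm.fit_distance_model(results["dyad_days"], pred)
            model_fit.fixed.to_csv(out / "distance_model_fixed.csv")
            (out / "distance_model_variance.json").write_text(
                json.dumps(model_fit.variance_shares, indent=2)
            )
            files += [out / "distance_model_fixed.csv", out / "distance_model_variance.json"]
        results["distance_model"] = model_fit

    _write_report(out, results)
    files.append(out / "report.md")
    cfg_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in vars(config.scenario).items()}, sort_keys=True
        ).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(
        config_hash=cfg_hash,
        stage_seeds=seeds,
        checksums={str(f.relative_to(out)): _checksum(f) for f in files if f.exists()},
    )
    (out / "manifest.json").write_text(
        json.dumps(
            {"config_hash": manifest.config_hash, "stage_seeds": manifest.stage_seeds,
             "checksums": manifest.checksums, "version": manifest.version}, indent=2)
    )
    return manifest, results


def _write_report(out: Path, results: dict) -> None:
    lines = ["# dialectscope run report", ""]
    if "classification_matrix" in results:
        lines += ["## Pairwise classification success",
                  "(validation below diagonal, held-out test above)", "",
                  results["classification_matrix"].round(3).to_markdown(), ""]
    if "assortativity" in results:
        a = results["assortativity"]
        lines += ["## Proximity-network assortativity (rearing population)",
                  f"r = {a.r:.3f}, permutation p = {a.p_perm:.4f} "
                  f"(conservative {a.p_conservative:.4f}, {a.n_permutations} permutations)", ""]
    if "daily_series" in results:
        for attr, (series, trend) in results["daily_series"].items():
            lines += [f"daily assortment by {attr}: slope {trend['slope']:.4f} "
                      f"(final-day r = {series['r'].iloc[-1]:.3f})"]
        lines.append("")
    if "assortment" in results:
        s = results["assortment"]
        lines += ["## Pair assortment",
                  f"{s.n_assortative}/{s.n_pairs} assortative ({s.percentage_rounded}%), "
                  f"binomial p = {s.binomial_p_two_tailed:.2e}", ""]
    if "hypothesis_correlations" in results:
        lines += ["## Hypothesis correlations"]
        for name, d in results["hypothesis_correlations"].items():
            lines.append(f"- {name}: r = {d['r']:.3f} (p = {d['p']:.2e})")
        mix = results.get("mixture")
        if mix:
            w = ", ".join(f"{k}={v:.2f}" for k, v in mix.weights.items())
            lines.append(f"- best mixture: {w} (r = {mix.achieved_correlation:.3f})")
        lines.append("")
    fit = results.get("distance_model")
    if fit is not None:
        lines += ["## Distance model", "", fit.fixed.round(4).to_markdown(), "",
                  "variance shares (%): "
                  + ", ".join(f"{k}={v:.1f}" for k, v in fit.variance_shares.items()), ""]
    (out / "report.md").write_text("\n".join(lines))
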