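"""End-to-end reproducible run: simulate -> score -> embed -> graph ->
communities -> predict -> stats.

:func:`run_pipeline` executes every stage in order on a synthetic cohort,
writes each intermediate artifact as a plain-text file under the output
directory and returns a JSON-serializable report with scorecard group
summaries, the community table and the model-comparison table. The report
is deterministic under the configured seed; the timestamp is isolated in a
single header field so the remainder can be compared byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as fio
from .bayes import compare_models
from .cohort import (GroupProfile, make_default_profiles, make_lexicon,
                     simulate_cohort, SyntheticLexicon)
from .embedding import attach_covariates, cosine_adjacency, embed_sequences
from .features import feature_table, frontal_target, score_cohort
from .lexicon import FrequencyLexicon
from .sbm import community_contrasts, fit_sbm, profile_communities
from .stats import ancova

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("fluencygraph")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (seed propagates everywhere)."""

    out_dir: str
    seed: int = 0
    n_per_group: Optional[int] = 30     # None keeps each profile's own n
    lexicon_path: Optional[str] = None  # None: generate a synthetic lexicon
    lexicon_size: int = 1000
    zipf_s: float = 1.0
    p_stay: float = 0.4
    frontal_style_seed: Optional[int] = None  # distinct lexicon for LF/RF
    embed_d: int = 2048
    sbm_Q: int = 8
    max_blocks: int = 25
    n_sweeps: int = 10
    k_project: int = 64
    mcmc: tuple[int, int, int] = (1000, 1000, 2)
    family_alpha: float = 0.05
    mwu_divisor: int = 40

    def profiles(self) -> list[GroupProfile]:
        profs = make_default_profiles()
        if self.n_per_group is not None:
            for p in profs:
                p.n = self.n_per_group
        return profs


def _stage(name: str):
    def wrap(fn):
        def inner(ctx, *args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(ctx, *args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            ctx["timings"][name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", name, ctx["timings"][name])
            return out
        return inner
    return wrap


@_stage("simulate")
def _simulate(ctx, cfg: RunConfig):
    if cfg.lexicon_path is not None:
        path = Path(cfg.lexicon_path)
        if not path.exists():
            raise FileNotFoundError(f"lexicon path does not exist: {path}")
        lex_freq = FrequencyLexicon.from_tsv(path)
        entries = sorted(lex_freq.frequencies.items(), key=lambda kv: -kv[1])
        lexicon = SyntheticLexicon(list(entries), seed=cfg.seed)
    else:
        lexicon = make_lexicon(cfg.lexicon_size, cfg.zipf_s, seed=cfg.seed)
    style = None
    if cfg.frontal_style_seed is not None:
        style_lex = make_lexicon(cfg.lexicon_size, cfg.zipf_s,
                                 seed=cfg.frontal_style_seed)
        style = {"LF": style_lex, "RF": style_lex}
    participants, transcripts = simulate_cohort(
        cfg.profiles(), lexicon, seed=cfg.seed, p_stay=cfg.p_stay,
        group_lexicons=style,
    )
    ctx.update(lexicon=lexicon, participants=participants,
               transcripts=transcripts, style=style)
    out = ctx["out"]
    lexicon.to_frequency_lexicon().to_tsv(out / "lexicon.tsv")
    fio.write_metadata(participants, out / "metadata.tsv")
    fio.write_transcripts(transcripts, out / "transcripts.jsonl")


@_stage("score")
def _score(ctx, cfg: RunConfig):
    lexica = [ctx["lexicon"].to_frequency_lexicon()]
    if ctx["style"]:
        lexica.append(next(iter(ctx["style"].values())).to_frequency_lexicon())
    cards, threshold = score_cohort(ctx["transcripts"], lexica)
    ctx.update(scorecards=cards, threshold=threshold)
    fio.write_scorecards(cards, ctx["out"] / "scorecards.tsv")


@_stage("embed")
def _embed(ctx, cfg: RunConfig):
    E = embed_sequences(ctx["transcripts"], d=cfg.embed_d, seed=cfg.seed)
    ctx["embeddings"] = E
    fio.write_embeddings(E, ctx["out"] / "embeddings.tsv")


@_stage("graph")
def _graph(ctx, cfg: RunConfig):
    G = cosine_adjacency(ctx["embeddings"])
    attach_covariates(G, ctx["participants"], ctx["transcripts"],
                      ctx["lexicon"].to_frequency_lexicon())
    ctx["graph"] = G
    fio.write_edges(G, ctx["out"] / "edges.tsv")


@_stage("communities")
def _communities(ctx, cfg: RunConfig):
    part = fit_sbm(ctx["graph"], max_blocks=cfg.max_blocks,
                   n_sweeps=cfg.n_sweeps, seed=cfg.seed, Q=cfg.sbm_Q)
    profiles = profile_communities(part, ctx["participants"],
                                   ctx["transcripts"], ctx["scorecards"])
    flu = pd.DataFrame(
        {"fluency": [c.correct_words for c in ctx["scorecards"]]},
        index=[c.participant_id for c in ctx["scorecards"]],
    )
    contrasts = community_contrasts(part, ctx["participants"], flu,
                                    alpha_family=cfg.family_alpha,
                                    divisor=cfg.mwu_divisor)
    ctx.update(partition=part, community_profiles=profiles,
               community_contrasts=contrasts)
    out = ctx["out"]
    pd.DataFrame({"participant_id": part.participant_ids,
                  "block": part.assignment}).to_csv(
        out / "partition.tsv", sep="\t", index=False)
    with open(out / "communities.json", "w") as fh:
        json.dump([p.__dict__ for p in profiles], fh, indent=1, default=float)


@_stage("predict")
def _predict(ctx, cfg: RunConfig):
    cards, participants = ctx["scorecards"], ctx["participants"]
    feats = feature_table(participants, cards)
    y = frontal_target(participants)
    table = compare_models(feats, y, embeddings=ctx["embeddings"],
                           seed=cfg.seed, k_project=cfg.k_project,
                           mcmc=cfg.mcmc)
    ctx["model_comparison"] = table
    table.to_csv(ctx["out"] / "model_comparison.tsv", sep="\t", index=False)


@_stage("stats")
def _stats(ctx, cfg: RunConfig):
    cards, participants = ctx["scorecards"], ctx["participants"]
    groups = np.array([p.group for p in participants])
    covs = np.column_stack([[p.age for p in participants],
                            [p.nart for p in participants]])
    results = {}
    for var in ("correct_words", "pct_rulebreak", "pct_perseveration",
                "pct_lowfreq"):
        vals = np.array([np.nan_to_num(getattr(c, var)) for c in cards])
        r = ancova(vals, groups, covs)
        results[var] = dict(F=r.F, df_between=r.df_between,
                            df_within=r.df_within, p=r.p,
                            partial_eta_sq=r.partial_eta_sq,
                            adjusted_means=r.adjusted_means)
    ctx["ancova"] = results


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the JSON run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"out": out, "timings": {}}
    _simulate(ctx, config)
    _score(ctx, config)
    _embed(ctx, config)
    _graph(ctx, config)
    _communities(ctx, config)
    _predict(ctx, config)
    _stats(ctx, config)

    cards = ctx["scorecards"]
    df = pd.DataFrame([c.as_dict() for c in cards])
    df["group"] = [p.group for p in ctx["participants"]]
    group_summary = {
        g: {col: [round(float(sub[col].mean()), 4),
                  round(float(sub[col].std(ddof=1)), 4)]
            for col in ("correct_words", "pct_rulebreak", "pct_perseveration",
                        "pct_lowfreq", "mean_cluster_size", "relative_switches")}
        for g, sub in df.groupby("group")
    }
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "meta": {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "seed": config.seed,
            "n_participants": len(cards),
            "timings_s": ctx["timings"],
        },
        "lowfreq_threshold": ctx["threshold"],
        "group_summary": group_summary,
        "ancova": ctx["ancova"],
        "communities": {
            "n_blocks": ctx["partition"].n_blocks,
            "description_length": ctx["partition"].description_length,
            "profiles": [p.__dict__ for p in ctx["community_profiles"]],
            "n_significant_contrasts": int(
                ctx["community_contrasts"]["significant"].sum()),
        },
        "model_comparison": ctx["model_comparison"].to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
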