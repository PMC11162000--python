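"""End-to-end orchestration: tokenize -> embed -> curate -> graph -> model
-> evaluate, plus the ablation harnesses (stack combinations, class
imbalance, corpus variants).

A single config seed fans out to per-stage derived seeds (stable hashing
of stage names), so any stage can be re-run in isolation and a persisted
config re-runs to identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import curation, embedding, metrics, models, pairgraph, synthetic
from .curation import CorpusSpec
from .embedding import SkipgramConfig
from .metrics import CVPlan
from .models import TrainConfig
from .synthetic import SynthConfig, derive_seed

__all__ = [
    "RunConfig",
    "PipelineResult",
    "CORPUS_VARIANTS",
    "run_end_to_end",
    "crossvalidate",
    "ablate_stacks",
    "ablate_imbalance",
    "ablate_corpus",
    "audit_corpus_entities",
]

log = logging.getLogger("sgcpi")

#: corpus variant -> (entity scope, dedupe, oov policy). ``all`` scope
#: pre-trains on every entity (corpus_2-style); ``train_only`` excludes
#: test entities from the corpus (leak-free corpus_3_only-style), making
#: the OOV policy matter for held-out entities.
CORPUS_VARIANTS: dict[str, tuple[str, str, str]] = {
    "baseline": ("all", "none", "averaged"),
    "train_random_oov": ("train_only", "none", "random"),
    "train_averaged_oov": ("train_only", "none", "averaged"),
    "dedup": ("all", "redundancy_filtered", "averaged"),
    "exclude_test": ("train_only", "none", "averaged"),
}


@dataclass(frozen=True)
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    embed: SkipgramConfig = field(default_factory=SkipgramConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv: CVPlan = field(default_factory=CVPlan)
    corpus_variant: str = "baseline"
    atoms_only: bool = False
    knn: int = 10
    graph_mode: str = "binary"
    stack: str = "SGCN+SGCN+SGCN"
    hidden: int = 64
    split_mode: str = "entity_disjoint"
    seed: int = 7
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(listify(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["synth"] = SynthConfig(**_tupled(raw.get("synth", {})))
        raw["embed"] = SkipgramConfig(**raw.get("embed", {}))
        raw["train"] = TrainConfig(**raw.get("train", {}))
        raw["cv"] = CVPlan(**raw.get("cv", {}))
        return cls(**raw)


def _tupled(d: dict) -> dict:
    out = dict(d)
    for k in ("ic50_positive_range", "ic50_negative_range", "seq_length_range"):
        if k in out and out[k] is not None:
            out[k] = tuple(out[k])
    return out


@dataclass
class PipelineResult:
    config: RunConfig
    test_metrics: dict[str, float]
    n_train: int
    n_test: int
    model_info: dict
    scores: pd.DataFrame  # pair_id, y, score
    artifacts: dict[str, str] = field(default_factory=dict)


def _derived(config: RunConfig, stage: str) -> int:
    return derive_seed(config.seed, stage)


def _build_embeddings(config: RunConfig, fixture):
    """Corpus assembly + per-modality SGNS training + entity vectors."""
    scope, dedupe, oov_policy = CORPUS_VARIANTS[config.corpus_variant]
    exclude = fixture.test_entity_ids if scope == "train_only" else frozenset()
    spec = CorpusSpec(
        name=config.corpus_variant, dedupe=dedupe,
        exclude_entities=frozenset(exclude), oov_policy=oov_policy,
    )
    comp_corpus, prot_corpus, provenance = curation.build_corpus(
        spec, fixture.compounds, fixture.proteins, atoms_only=config.atoms_only
    )
    tables = {}
    corpora = {"compound": comp_corpus, "protein": prot_corpus}
    for modality, corpus in corpora.items():
        vocab = embedding.build_vocab(corpus, min_count=1)
        cfg = replace(config.embed, seed=_derived(config, f"embed-{modality}"))
        tables[modality], _ = embedding.train_skipgram(corpus, vocab, cfg)
    rng = np.random.default_rng(_derived(config, "oov"))
    vectors: dict[str, np.ndarray] = {}
    oov_fracs: dict[str, float] = {}
    for c in fixture.compounds:
        toks = curation.tokenize_smiles(
            c.smiles_canonical, entity_id=c.id, atoms_only=config.atoms_only
        )
        emb = embedding.embed_entity(toks, tables["compound"], oov_policy, rng)
        vectors[c.id], oov_fracs[c.id] = emb.vector, emb.oov_fraction
    for p in fixture.proteins:
        toks = curation.tokenize_protein(p.sequence, entity_id=p.id)
        emb = embedding.embed_entity(toks, tables["protein"], oov_policy, rng)
        vectors[p.id], oov_fracs[p.id] = emb.vector, emb.oov_fraction
    return tables, vectors, oov_fracs, provenance, corpora


def _pair_nodes(records: pd.DataFrame, vectors, split: str) -> list[pairgraph.PairNode]:
    nodes = []
    for _, row in records.iterrows():
        label = {"positive": 1, "negative": 0}.get(row["label"])
        if label is None:
            continue
        feats = pairgraph.concat_features(
            vectors[row["compound_id"]], vectors[row["protein_id"]]
        )
        nodes.append(
            pairgraph.PairNode(
                pair_id=f"{row['compound_id']}::{row['protein_id']}",
                compound_id=row["compound_id"],
                protein_id=row["protein_id"],
                features=feats,
                label=label,
                split=split,
            )
        )
    return nodes


def _train_and_score(graph, stack_str: str, hidden: int, train_cfg: TrainConfig):
    """Train the requested stack on the train mask, score every node."""
    stack = models.parse_stack(stack_str, hidden=hidden)
    y = graph.y
    train_mask = graph.mask("train")
    if stack.is_pure_sgc:
        params = models.train_pure_sgc(
            graph.S, graph.X, y, stack.K, train_mask, train_cfg
        )
        probs = models.sgc_forward(
            graph.S, graph.X, stack.K, params.head_w, params.head_b
        )
    else:
        params = models.train_stack(graph.S, graph.X, y, stack, train_mask, train_cfg)
        probs = models.stack_forward(graph.S, graph.X, stack, params)
    return stack, params, probs


def run_end_to_end(config: RunConfig | None = None) -> PipelineResult:
    """Execute the full pipeline on a synthetic fixture and evaluate on the
    held-out split; writes artifacts when ``config.out_dir`` is set."""
    config = config or RunConfig()
    fixture = synthetic.make_fixture(config.synth, mode=config.split_mode)
    log.info(
        "fixture: %d train / %d test pairs", len(fixture.train_records),
        len(fixture.test_records),
    )
    tables, vectors, oov_fracs, corpus_prov, _ = _build_embeddings(config, fixture)
    train_nodes = _pair_nodes(fixture.train_records, vectors, "train")
    test_nodes = _pair_nodes(fixture.test_records, vectors, "test")
    train_graph = pairgraph.build_pair_graph(
        train_nodes, k=config.knn, mode=config.graph_mode
    )
    graph = pairgraph.attach_test_nodes(train_graph, test_nodes, k=config.knn)
    train_cfg = replace(config.train, seed=_derived(config, "train"))
    stack, params, probs = _train_and_score(
        graph, config.stack, config.hidden, train_cfg
    )
    test_mask = graph.mask("test")
    y = graph.y
    test_metrics = metrics.all_metrics(y[test_mask], probs[test_mask])
    scores = pd.DataFrame(
        {
            "pair_id": [nd.pair_id for nd in graph.nodes],
            "y": y,
            "score": probs,
            "split": [nd.split for nd in graph.nodes],
        }
    )
    result = PipelineResult(
        config=config,
        test_metrics=test_metrics,
        n_train=int((~test_mask).sum()),
        n_test=int(test_mask.sum()),
        model_info=dict(params.info),
        scores=scores,
    )
    if config.out_dir:
        result.artifacts = _write_artifacts(
            config, tables, graph, stack, params, scores, test_metrics, corpus_prov
        )
    return result


def _write_artifacts(config, tables, graph, stack, params, scores, test_metrics,
                     corpus_prov) -> dict[str, str]:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    paths = {}
    for modality, table in tables.items():
        p = os.path.join(out, f"{modality}_embeddings.txt")
        embedding.save_word2vec_text(table, p)
        paths[f"{modality}_embeddings"] = p
    paths["graph_edges"] = os.path.join(out, "graph_edges.tsv")
    paths["graph_nodes"] = os.path.join(out, "graph_nodes.tsv")
    pairgraph.save_edge_list(graph, paths["graph_edges"], paths["graph_nodes"])
    paths["model"] = os.path.join(out, "model.json")
    with open(paths["model"], "w") as fh:
        json.dump(
            {
                "stack": str(stack),
                "hidden": stack.hidden,
                "seed": params.seed,
                "head_w": params.head_w.tolist(),
                "head_b": params.head_b,
                "thetas": [t.tolist() for t in params.thetas],
                "info": {k: v for k, v in params.info.items()
                         if k != "loss_trajectory"},
            },
            fh,
        )
    paths["scores"] = os.path.join(out, "scores.tsv")
    scores.to_csv(paths["scores"], sep="\t", index=False)
    paths["report"] = os.path.join(out, "report.json")
    with open(paths["report"], "w") as fh:
        json.dump({"test_metrics": test_metrics, "corpus": corpus_prov}, fh, indent=2)
    paths["provenance"] = os.path.join(out, "provenance.yaml")
    config.to_yaml(paths["provenance"])
    return paths


def crossvalidate(config: RunConfig | None = None) -> metrics.MetricsReport:
    """Repeated stratified CV on the training split's pair nodes.

    Embeddings are trained once on the configured corpus; each fold
    rebuilds the similarity graph from the fold's training nodes and
    attaches the fold's held-out nodes transductively.
    """
    config = config or RunConfig()
    fixture = synthetic.make_fixture(config.synth, mode=config.split_mode)
    _, vectors, *_ = _build_embeddings(config, fixture)
    nodes = _pair_nodes(fixture.train_records, vectors, "train")
    y = np.array([nd.label for nd in nodes])
    train_cfg = replace(config.train, seed=_derived(config, "train"))
    plan = replace(config.cv, seed=_derived(config, "cv"))

    def fit_fn(train_idx):
        sub = [nodes[i] for i in train_idx]
        g = pairgraph.build_pair_graph(sub, k=min(config.knn, len(sub) - 1),
                                       mode=config.graph_mode)
        return g

    def eval_fn(g, test_idx):
        held = [
            pairgraph.PairNode(
                pair_id=nodes[i].pair_id, compound_id=nodes[i].compound_id,
                protein_id=nodes[i].protein_id, features=nodes[i].features,
                label=nodes[i].label, split="test",
            )
            for i in test_idx
        ]
        full = pairgraph.attach_test_nodes(g, held, k=min(config.knn, g.n))
        _, _, probs = _train_and_score(full, config.stack, config.hidden, train_cfg)
        m = full.mask("test")
        return metrics.all_metrics(full.y[m], probs[m])

    return metrics.repeated_stratified_cv(y, plan, fit_fn, eval_fn)


def ablate_stacks(config: RunConfig, stack_list: list[str]) -> pd.DataFrame:
    """One pipeline evaluation per stack string; embeddings and graph are
    shared so rows differ only in the classifier stack."""
    config = config or RunConfig()
    for s in stack_list:
        models.parse_stack(s)  # fail fast, naming the offender
    fixture = synthetic.make_fixture(config.synth, mode=config.split_mode)
    _, vectors, *_ = _build_embeddings(config, fixture)
    train_nodes = _pair_nodes(fixture.train_records, vectors, "train")
    test_nodes = _pair_nodes(fixture.test_records, vectors, "test")
    train_graph = pairgraph.build_pair_graph(train_nodes, k=config.knn,
                                             mode=config.graph_mode)
    graph = pairgraph.attach_test_nodes(train_graph, test_nodes, k=config.knn)
    train_cfg = replace(config.train, seed=_derived(config, "train"))
    rows = []
    test_mask = graph.mask("test")
    for s in stack_list:
        stack, params, probs = _train_and_score(graph, s, config.hidden, train_cfg)
        m = metrics.all_metrics(graph.y[test_mask], probs[test_mask])
        rows.append(
            {
                "stack": s,
                **m,
                "propagation_precomputes": params.info["propagation_precomputes"],
                "propagations_per_epoch": params.info["propagations_per_epoch"],
                "total_propagations": params.info["total_propagations"],
            }
        )
    return pd.DataFrame(rows)


def _parse_ratio(ratio) -> float:
    """Accept 0.2, "1:5" etc.; returns positives per negative."""
    if isinstance(ratio, str):
        pos, neg = ratio.split(":")
        return float(pos) / float(neg)
    return float(ratio)


def ablate_imbalance(config: RunConfig, ratios: list) -> pd.DataFrame:
    """Regenerate fixtures at each positive:negative ratio and re-run."""
    rows = []
    for ratio in ratios:
        r = _parse_ratio(ratio)
        cfg = replace(config, synth=replace(config.synth, pos_neg_ratio=r),
                      out_dir=None)
        res = run_end_to_end(cfg)
        rows.append({"ratio": str(ratio), "pos_per_neg": r, **res.test_metrics,
                     "n_test": res.n_test})
    return pd.DataFrame(rows)


def audit_corpus_entities(corpora: dict, entity_ids: frozenset[str]) -> int:
    """Number of corpus sentences belonging to the given entities (leak audit)."""
    return sum(
        1
        for corpus in corpora.values()
        for sent in corpus
        if sent.entity_id in entity_ids
    )


def ablate_corpus(config: RunConfig, variants: list[str]) -> pd.DataFrame:
    """One pipeline run per corpus variant (scope / dedupe / OOV policy),
    with a per-row audit of test-entity sentences left in the corpus."""
    rows = []
    for variant in variants:
        if variant not in CORPUS_VARIANTS:
            raise ValueError(f"unknown corpus variant {variant!r}")
        cfg = replace(config, corpus_variant=variant, out_dir=None)
        fixture = synthetic.make_fixture(cfg.synth, mode=cfg.split_mode)
        _, vectors, oov_fracs, prov, corpora = _build_embeddings(cfg, fixture)
        res = run_end_to_end(cfg)
        audit = audit_corpus_entities(corpora, fixture.test_entity_ids)
        test_ids = [c.id for c in fixture.test_compounds] + [
            p.id for p in fixture.test_proteins
        ]
        mean_oov = float(np.mean([oov_fracs[i] for i in test_ids])) if test_ids else 0.0
        rows.append(
            {
                "variant": variant,
                **res.test_metrics,
                "test_sentences_in_corpus": audit,
                "mean_test_oov_fraction": mean_oov,
                "corpus_compounds": prov["n_compounds"],
                "corpus_proteins": prov["n_proteins"],
            }
        )
    return pd.DataFrame(rows)
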