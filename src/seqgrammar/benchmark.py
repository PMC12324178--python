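"""Reference benchmark recipe: simulate, train small models, evaluate.

This module pins the package's reference evaluation conditions for the 10x
3' layout — simulator settings (default error rates, 100-500 bp inserts,
0-70 bp flanks, a 6,500-barcode whitelist), reduced CPU-sized model
hyperparameters, and the three headline metrics:

* structural-filtering accuracy (valid/invalid call vs ground truth, in
  both the hybrid and CRF-only annotation modes),
* demultiplexing efficiency (fraction of structurally valid reads uniquely
  assigned to a whitelist barcode at edit distance <= 2),
* concatemer sub-fragment recovery (fraction of true sub-fragments matched
  by the CRF model's concatemer calls, requiring the right orientation and
  >= 75% span overlap).

Training uses a 50,000-read set (85% canonical, 15% artifacts across all
eight patterns, both orientations).  The fast softmax model trains for two
passes (the second at a lower learning rate); the CRF variant warm-starts
from the fast model's encoder and fine-tunes for one pass to learn its
transition parameters.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from seqgrammar.annotate import annotate_read, annotate_reads
from seqgrammar.demux import demultiplex
from seqgrammar.layout import LibraryLayout, builtin_layout
from seqgrammar.model import ModelConfig, SequenceAnnotator, TrainConfig
from seqgrammar.simulate import SimulationConfig, random_whitelist, simulate_reads

N_TRAIN = 50_000
N_EVAL_CANONICAL = 20_000
N_EVAL_ARTIFACT = 2_000
WHITELIST_SIZE = 6_500
ARTIFACT_TRAIN_FRACTION = 0.15
TOKEN_BUDGET = 65_536
OVERLAP_THRESHOLD = 0.75


def reference_model_config(head: str, n_labels: int) -> ModelConfig:
    """Reduced CPU-sized architecture used throughout the benchmarks."""
    return ModelConfig(
        n_labels=n_labels,
        embed_dim=8,
        conv_layers=((48, 7),),
        lstm_layers=(32,),
        dropout=0.0,
        head=head,
    )


def train_reference_models(
    layout: LibraryLayout | None = None,
    whitelist: tuple[str, ...] | None = None,
    seed: int = 0,
    n_train: int = N_TRAIN,
    progress=None,
) -> tuple[SequenceAnnotator, SequenceAnnotator, LibraryLayout, tuple[str, ...]]:
    """Train the fast softmax model and the CRF variant on one shared set."""
    layout = layout or builtin_layout()
    if whitelist is None:
        whitelist = random_whitelist(WHITELIST_SIZE, rng=seed)
    schema = layout.label_schema
    cfg = SimulationConfig(
        layout=layout, n_reads=n_train, whitelist=whitelist, seed=seed + 1
    )
    reads = simulate_reads(cfg, artifact_fraction=ARTIFACT_TRAIN_FRACTION)
    if progress:
        progress(f"simulated {len(reads)} training reads")
    fast = SequenceAnnotator(
        reference_model_config("softmax", len(schema)), schema, seed=seed
    )
    fast.fit(
        reads,
        TrainConfig(epochs=2, learning_rate=0.01, lr_decay=0.3, seed=seed),
    )
    if progress:
        progress(f"fast model trained (token acc {fast.history[-1]['accuracy']:.4f})")
    crf = SequenceAnnotator(
        reference_model_config("crf", len(schema)), schema, seed=seed + 1
    )
    crf.warm_start_from(fast)
    crf.fit(
        reads,
        TrainConfig(epochs=1, learning_rate=0.004, seed=seed + 1),
    )
    if progress:
        progress(f"crf model trained (token acc {crf.history[-1]['accuracy']:.4f})")
    return fast, crf, layout, whitelist


@dataclass
class StructuralEvaluation:
    accuracy_by_mode: dict  # mode -> percent
    valid_table: pd.DataFrame  # HYB-mode valid annotations
    sequences: dict  # read_id -> sequence
    truth_cbc: dict  # read_id -> generating barcode
    n_reads: int


def evaluate_structural_accuracy(
    fast: SequenceAnnotator,
    crf: SequenceAnnotator,
    layout: LibraryLayout,
    whitelist: tuple[str, ...],
    seed: int,
    n_canonical: int = N_EVAL_CANONICAL,
    n_artifact: int = N_EVAL_ARTIFACT,
) -> StructuralEvaluation:
    """Valid/invalid call accuracy on a held-out canonical + artifact set."""
    canon = simulate_reads(
        SimulationConfig(
            layout=layout, n_reads=n_canonical, whitelist=whitelist, seed=seed + 7
        )
    )
    arts = simulate_reads(
        SimulationConfig(
            layout=layout, n_reads=n_artifact, whitelist=whitelist, seed=seed + 8
        ),
        artifact_fraction=1.0,
    )
    reads = canon + arts
    ids = [r.read_id for r in reads]
    seqs = [r.sequence for r in reads]
    truth_valid = {r.read_id: r.artifact_pattern is None for r in reads}
    accuracy = {}
    hyb_valid = None
    for mode in ("HYB", "CRF"):
        valid, invalid = annotate_reads(
            zip(ids, seqs), fast, crf, layout, mode=mode, token_budget=TOKEN_BUDGET
        )
        n_ok = sum(1 for rid in valid.read_id if truth_valid[rid]) + sum(
            1 for rid in invalid.read_id if not truth_valid[rid]
        )
        accuracy[mode] = 100.0 * n_ok / len(reads)
        if mode == "HYB":
            hyb_valid = valid
    return StructuralEvaluation(
        accuracy_by_mode=accuracy,
        valid_table=hyb_valid,
        sequences=dict(zip(ids, seqs)),
        truth_cbc={r.read_id: r.truth_cbc for r in reads},
        n_reads=len(reads),
    )


def evaluate_demux_efficiency(
    evaluation: StructuralEvaluation,
    whitelist: tuple[str, ...],
    max_dist: int = 2,
) -> dict:
    """Unique-assignment fraction over the structurally valid reads."""
    assignments = demultiplex(
        evaluation.valid_table, evaluation.sequences, whitelist, max_dist
    )
    assigned = assignments[assignments["status"] == "assigned"]
    n = len(assignments)
    n_correct = sum(
        rec.corrected == evaluation.truth_cbc.get(rec.read_id)
        for rec in assigned.itertuples(index=False)
    )
    return {
        "percent_assigned": 100.0 * len(assigned) / max(n, 1),
        "percent_assigned_correctly": 100.0 * n_correct / max(n, 1),
        "n_valid": n,
    }


def evaluate_fragment_recovery(
    crf: SequenceAnnotator,
    layout: LibraryLayout,
    whitelist: tuple[str, ...],
    seed: int,
    n_reads: int = N_EVAL_ARTIFACT,
) -> dict:
    """Sub-fragment recovery from concatemers via CRF structural calls.

    A true sub-fragment counts as recovered when the concatemer call holds
    a sub-span with the same orientation overlapping it by at least
    ``OVERLAP_THRESHOLD`` (Jaccard).
    """
    arts = simulate_reads(
        SimulationConfig(
            layout=layout, n_reads=n_reads, whitelist=whitelist, seed=seed + 9
        ),
        artifact_fraction=1.0,
    )
    preds = crf.predict([r.sequence for r in arts], token_budget=TOKEN_BUDGET)
    total = recovered = 0
    for r, (labels, conf) in zip(arts, preds):
        anno = annotate_read(r.read_id, labels, conf, layout)
        pred = (
            list(anno.call.sub_spans) if anno.call.status == "concatemer" else []
        )
        used = [False] * len(pred)
        for ts, te, to in r.fragments:
            total += 1
            for i, (ps, pe, po) in enumerate(pred):
                if used[i] or po != to:
                    continue
                inter = max(0, min(te, pe) - max(ts, ps))
                union = max(te, pe) - min(ts, ps)
                if union > 0 and inter / union >= OVERLAP_THRESHOLD:
                    used[i] = True
                    recovered += 1
                    break
    return {
        "percent_recovered": 100.0 * recovered / max(total, 1),
        "n_fragments": total,
    }
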