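"""Pre-training, class-balanced fine-tuning, and domain-adversarial transfer.

Pre-training follows the masked-language-model recipe: the genome is tiled
into non-overlapping sequences of at most 5,000 bp (runs of N excluded),
15% of the usable tokens of each input are selected, and selected tokens
are replaced by MASK / a random k-mer / kept unchanged in an 80/10/10
split; the loss is cross-entropy at the selected positions only.

Fine-tuning balances the (heavily negative-skewed) training set by window-
shift oversampling of the minority class, then trains encoder + TextCNN
end-to-end, tracking AUROC/AUPR/F1 per epoch and keeping the checkpoint
with the best validation AUROC.

Cross-cell-line transfer uses a domain-adversarial network (DANN): a
domain discriminator behind a gradient reversal layer sees pooled encoder
features from both domains, so the encoder is pushed toward features the
discriminator cannot use, realizing the minimax objective
``min_enc  L_class − λ·L_domain`` while the discriminator minimizes
``L_domain``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from . import seqio
from .nn import autograd as ag
from .nn.model import EPIModel
from .nn.optim import AdamW
from .tokenizer import Vocabulary, assemble_pair, kmerize

IGNORE_INDEX = -100
MASK_RATE = 0.15
CORPUS_MAX_LEN = 5000


# ---------------------------------------------------------------------------
# pre-training corpus and masking
# ---------------------------------------------------------------------------

def build_pretrain_corpus(genome: Mapping[str, str], max_len: int = CORPUS_MAX_LEN,
                          seed: int = 0, min_len: int = 20) -> list[str]:
    """Tile a genome into non-overlapping N-free sequences of <= ``max_len`` bp.

    Contigs are processed in mapping order; each N-free segment is cut into
    consecutive chunks of ``max_len`` (a short terminal chunk is kept when at
    least ``min_len``).  The seed deterministically shuffles the final list.
    """
    corpus: list[str] = []
    for seq in genome.values():
        for segment in seq.split("N"):
            for i in range(0, len(segment), max_len):
                chunk = segment[i : i + max_len]
                if len(chunk) >= min_len:
                    corpus.append(chunk)
    rng = np.random.default_rng(seed)
    rng.shuffle(corpus)
    return corpus


@dataclasses.dataclass
class MaskingPlan:
    positions: np.ndarray   # indices selected for masking
    replacement: np.ndarray # per-position action: 0=MASK, 1=random, 2=keep
    rate: float
    seed: int


def mask_tokens(ids: np.ndarray, vocab: Vocabulary, rate: float = MASK_RATE,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray, MaskingPlan]:
    """BERT-style masking of ``round(rate x usable)`` non-special tokens (min 1).

    Returns (masked ids, labels, plan); labels carry the original id at the
    selected positions and IGNORE_INDEX elsewhere.
    """
    ids = np.asarray(ids)
    rng = np.random.default_rng(seed)
    usable = np.flatnonzero(ids >= vocab.n_specials)
    if usable.size == 0:
        raise ValueError("input contains no maskable (non-special) tokens")
    n_select = max(1, int(round(rate * usable.size)))
    positions = np.sort(rng.choice(usable, size=n_select, replace=False))
    actions = rng.choice(3, size=n_select, p=(0.8, 0.1, 0.1))
    masked = ids.copy()
    labels = np.full_like(ids, IGNORE_INDEX)
    labels[positions] = ids[positions]
    for pos, act in zip(positions, actions):
        if act == 0:
            masked[pos] = vocab.mask_id
        elif act == 1:
            masked[pos] = rng.integers(vocab.n_specials, len(vocab))
    return masked, labels, MaskingPlan(positions, actions, rate, seed)


# ---------------------------------------------------------------------------
# dataset encoding helpers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EncodedDataset:
    """Token-id matrix for equal-length assembled pairs, plus labels."""

    ids: np.ndarray      # (n, L) int64
    labels: np.ndarray   # (n,) int64

    def __len__(self) -> int:
        return self.ids.shape[0]


def encode_dataset(pairs: Sequence[tuple[str, str]], labels: Sequence[int],
                   vocab: Vocabulary) -> EncodedDataset:
    toks = [assemble_pair(e, p, vocab) for e, p in pairs]
    lengths = {len(t) for t in toks}
    if len(lengths) != 1:
        raise ValueError("all assembled pairs must have equal length")
    ids = np.stack([t.ids for t in toks])
    return EncodedDataset(ids=ids, labels=np.asarray(labels, dtype=np.int64))


def predict_probs(model: EPIModel, ids: np.ndarray, batch_size: int = 16
                  ) -> np.ndarray:
    """Interaction probability P(label=1) per row, evaluation mode."""
    out = []
    for i in range(0, len(ids), batch_size):
        res = model.forward_classify(ids[i : i + batch_size])
        out.append(res.class_probs[:, 1])
    return np.concatenate(out)


def classification_metrics(labels: np.ndarray, probs: np.ndarray) -> dict[str, float]:
    preds = (probs >= 0.5).astype(int)
    return {
        "auroc": float(roc_auc_score(labels, probs)),
        "aupr": float(average_precision_score(labels, probs)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
    }


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------

def _encode_corpus_batch(seqs: list[str], vocab: Vocabulary) -> tuple[np.ndarray, np.ndarray]:
    """Tokenize [CLS] + k-mers per sequence, PAD-pad to the batch maximum."""
    rows = []
    for s in seqs:
        ids = [vocab.cls_id] + [vocab.encode_kmer(m) for m in kmerize(s, vocab.k)]
        rows.append(np.array(ids, dtype=np.int64))
    L = max(len(r) for r in rows)
    ids = np.full((len(rows), L), vocab.pad_id, dtype=np.int64)
    for i, r in enumerate(rows):
        ids[i, : len(r)] = r
    return ids, ids == vocab.pad_id


def pretrain(corpus: Sequence[str], model: EPIModel, vocab: Vocabulary,
             n_steps: int = 200, batch_size: int = 8, lr: float = 3e-4,
             seed: int = 0, val_fraction: float = 0.1, eval_every: int = 50,
             patience: int | None = None) -> tuple[EPIModel, dict]:
    """Masked-language-model pre-training with an optional plateau stop.

    Returns the trained model and a trace dict with per-step training loss
    and periodic validation loss.
    """
    if not corpus:
        raise ValueError("empty pre-training corpus")
    rng = np.random.default_rng(seed)
    corpus = list(corpus)
    n_val = max(1, int(len(corpus) * val_fraction)) if len(corpus) > 2 else 0
    val_seqs = corpus[:n_val]
    train_seqs = corpus[n_val:] or corpus
    opt = AdamW(model.params, lr=lr, warmup_steps=min(20, n_steps // 10))
    trace = {"step_loss": [], "val_loss": [], "val_step": []}
    best_val, since_best = np.inf, 0

    def mlm_loss(seqs: list[str], step_seed: int, train: bool) -> float | None:
        ids, pad = _encode_corpus_batch(seqs, vocab)
        masked = np.empty_like(ids)
        labels = np.full_like(ids, IGNORE_INDEX)
        for r in range(ids.shape[0]):
            row = ids[r][~pad[r]]
            m, lab, _ = mask_tokens(row, vocab, seed=step_seed * 1000 + r)
            masked[r, : len(m)], masked[r, len(m):] = m, vocab.pad_id
            labels[r, : len(lab)] = lab
        hidden, _ = model.embed(masked, pad)
        logits = hidden @ model.params["mlm_w"] + model.params["mlm_b"]
        loss = ag.cross_entropy(logits, labels, ignore_index=IGNORE_INDEX)
        if train:
            model.zero_grad()
            loss.backward()
            opt.step()
        return float(loss.data)

    model.train()
    for step in range(n_steps):
        batch = [train_seqs[i] for i in
                 rng.choice(len(train_seqs), size=min(batch_size, len(train_seqs)),
                            replace=False)]
        loss = mlm_loss(batch, step, train=True)
        if not np.isfinite(loss):
            raise RuntimeError(f"pre-training diverged at step {step}: loss={loss}")
        trace["step_loss"].append(loss)
        if val_seqs and (step + 1) % eval_every == 0:
            model.eval()
            with ag.no_grad():
                vl = mlm_loss(val_seqs[:batch_size], 999_999, train=False)
            model.train()
            trace["val_loss"].append(vl)
            trace["val_step"].append(step + 1)
            if patience is not None:
                if vl < best_val - 1e-4:
                    best_val, since_best = vl, 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
    model.eval()
    return model, trace


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

def _shift_interval(iv: seqio.GenomicInterval, genome: Mapping[str, str],
                    shift_bound: int, rng: np.random.Generator) -> seqio.GenomicInterval:
    contig_len = len(genome[iv.chrom])
    for _ in range(1000):
        off = int(rng.integers(-shift_bound, shift_bound + 1))
        if off == 0:
            continue
        if iv.start + off >= 0 and iv.end + off <= contig_len:
            return seqio.GenomicInterval(iv.chrom, iv.start + off, iv.end + off, iv.strand)
    raise RuntimeError("could not find a valid shift offset inside the contig")


def augment_balance(records: Sequence[seqio.EPIRecord], genome: Mapping[str, str],
                    shift_bound: int = 50, seed: int = 0,
                    strategy: str = "shift",
                    ) -> tuple[list[seqio.EPIRecord], list[tuple[str, str]], list[int]]:
    """Oversample the minority class to a 1:1 ratio.

    ``strategy='shift'`` re-extracts minority windows displaced by a uniform
    offset in [-shift_bound, +shift_bound] (offsets overrunning the contig
    are resampled); ``strategy='duplicate'`` copies records verbatim.
    Returns (balanced records, their sequences, provenance) where provenance
    maps every output row to its source record index.
    """
    labels = np.array([r.label for r in records])
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one record of each class")
    rng = np.random.default_rng(seed)
    out_records = list(records)
    provenance = list(range(len(records)))
    minority = 1 if n_pos < n_neg else 0
    deficit = abs(n_neg - n_pos)
    pool = np.flatnonzero(labels == minority)
    for j in range(deficit):
        src = int(pool[j % len(pool)])
        r = records[src]
        if strategy == "shift":
            new = seqio.EPIRecord(
                enhancer=_shift_interval(r.enhancer, genome, shift_bound, rng),
                promoter=_shift_interval(r.promoter, genome, shift_bound, rng),
                label=r.label, cell_line=r.cell_line,
            )
        elif strategy == "duplicate":
            new = r
        else:
            raise ValueError(f"unknown balancing strategy {strategy!r}")
        out_records.append(new)
        provenance.append(src)
    sequences = seqio.extract_pair_sequences(genome, out_records)
    return out_records, sequences, provenance


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def _check_vocab(model: EPIModel, vocab: Vocabulary) -> None:
    if model.vocab_hash and model.vocab_hash != vocab.content_hash():
        raise ValueError("model checkpoint was built with a different vocabulary")


def finetune(train: EncodedDataset, validation: EncodedDataset, model: EPIModel,
             vocab: Vocabulary, epochs: int = 3, batch_size: int = 16,
             lr: float = 1e-3, seed: int = 0, max_steps_per_epoch: int | None = None,
             ) -> tuple[EPIModel, list[dict]]:
    """Supervised EPI training; best checkpoint by validation AUROC.

    Returns (best model, per-epoch metric trace with train loss and
    validation AUROC/AUPR/F1).
    """
    _check_vocab(model, vocab)
    rng = np.random.default_rng(seed)
    opt = AdamW(model.params, lr=lr, warmup_steps=10)
    trace: list[dict] = []
    best_auroc, best_state = -np.inf, None
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(train))
        if max_steps_per_epoch is not None:
            order = order[: max_steps_per_epoch * batch_size]
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            logits, _, _ = model.classify_logits(train.ids[idx])
            loss = ag.cross_entropy(logits, train.labels[idx])
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        probs = predict_probs(model, validation.ids, batch_size)
        metrics = classification_metrics(validation.labels, probs)
        metrics.update(epoch=epoch, train_loss=float(np.mean(losses)))
        trace.append(metrics)
        if metrics["auroc"] > best_auroc:
            best_auroc = metrics["auroc"]
            best_state = {k: v.data.copy() for k, v in model.params.items()}
    if best_state is not None:
        for k, v in best_state.items():
            model.params[k].data = v
    model.eval()
    return model, trace


# ---------------------------------------------------------------------------
# domain-adversarial transfer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TransferConfig:
    lam: float = 0.1
    schedule: str = "constant"   # or "ramp"
    source: str = "source"
    target: str = "target"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.schedule not in ("constant", "ramp"):
            raise ValueError("schedule must be 'constant' or 'ramp'")

    def lam_at(self, progress: float) -> float:
        if self.schedule == "constant":
            return self.lam
        return self.lam * (2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0)


@dataclasses.dataclass
class LossBreakdown:
    l_class: float
    l_domain: float
    lam: float

    @property
    def l_total(self) -> float:
        """The encoder's effective objective: L_class − λ·L_domain."""
        return self.l_class - self.lam * self.l_domain


def train_dann(source_train: EncodedDataset, source_val: EncodedDataset,
               target_ids: np.ndarray, model: EPIModel, vocab: Vocabulary,
               config: TransferConfig = TransferConfig(), epochs: int = 3,
               batch_size: int = 8, lr: float = 1e-3, seed: int = 0,
               ) -> tuple[EPIModel, list[LossBreakdown], list[dict]]:
    """DANN training: classification on labeled source, domain confusion on both.

    Each step runs the encoder on a mixed source+target batch; the TextCNN
    head sees only the source rows (classification loss), while the domain
    head — behind a gradient reversal layer scaled by λ — sees all rows.
    The sign flip lives entirely inside the GRL, so one optimizer step
    descends L_class + L_domain for the heads while the encoder effectively
    descends L_class − λ·L_domain.
    """
    _check_vocab(model, vocab)
    if len(target_ids) == 0:
        raise ValueError("target set must be non-empty")
    rng = np.random.default_rng(seed)
    opt = AdamW(model.params, lr=lr, warmup_steps=10)
    losses: list[LossBreakdown] = []
    metric_trace: list[dict] = []
    best_auroc, best_state = -np.inf, None
    steps_per_epoch = max(1, len(source_train) // batch_size)
    total_steps = epochs * steps_per_epoch
    step = 0
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(source_train))
        for i in range(0, steps_per_epoch * batch_size, batch_size):
            src_idx = order[i % len(order): i % len(order) + batch_size]
            if len(src_idx) == 0:
                continue
            tgt_idx = rng.choice(len(target_ids), size=min(batch_size, len(target_ids)),
                                 replace=len(target_ids) < batch_size)
            lam = config.lam_at(step / max(1, total_steps - 1))
            ids_all = np.concatenate([source_train.ids[src_idx], target_ids[tgt_idx]])
            hidden, _ = model.embed(ids_all)
            ns = len(src_idx)
            class_logits = model.cnn_logits(hidden[:ns])
            l_class = ag.cross_entropy(class_logits, source_train.labels[src_idx])
            dom_labels = np.array([0] * ns + [1] * len(tgt_idx))
            dom_logits = model.domain_logits(hidden, lam)
            l_domain = ag.cross_entropy(dom_logits, dom_labels)
            total = l_class + l_domain
            model.zero_grad()
            total.backward()
            opt.step()
            losses.append(LossBreakdown(float(l_class.data), float(l_domain.data), lam))
            step += 1
        model.eval()
        probs = predict_probs(model, source_val.ids, batch_size)
        metrics = classification_metrics(source_val.labels, probs)
        metrics["epoch"] = epoch
        metric_trace.append(metrics)
        if metrics["auroc"] > best_auroc:
            best_auroc = metrics["auroc"]
            best_state = {k: v.data.copy() for k, v in model.params.items()}
    if best_state is not None:
        for k, v in best_state.items():
            model.params[k].data = v
    model.eval()
    return model, losses, metric_trace
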