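"""Domain-adversarial transfer between two synthetic 'cell lines'.

Source and target share half their motif grammar and differ in background
GC.  A source-only model is compared with a DANN model that additionally
sees unlabeled target sequences through a gradient-reversed domain
discriminator; target AUROC should not get worse, and typically improves.
"""

import dataclasses

from epiattn import (ModelConfig, EPIModel, SynthSpec, TransferConfig,
                     Vocabulary, augment_balance, encode_dataset, finetune,
                     generate_domain_shift, split_dataset, train_dann)
from epiattn.training import classification_metrics, predict_probs

vocab = Vocabulary()
seed = 1
src_spec = SynthSpec(n_pos=80, n_neg=400, enh_len=240, prom_len=160,
                     mutation_rate=0.05, plant_prob=0.9, gc=0.4, seed=seed)
tgt_spec = dataclasses.replace(src_spec, gc=0.6, seed=seed + 500)
src, tgt = generate_domain_shift(src_spec, tgt_spec, shared_motif_fraction=0.5)
print(f"source motifs {src.spec.enh_motif}/{src.spec.prom_motif}, "
      f"target motifs {tgt.spec.enh_motif}/{tgt.spec.prom_motif}")

split = split_dataset(src.records, (0.8, 0.1, 0.1), seed=seed)
index = {id(r): i for i, r in enumerate(src.records)}
bal_recs, bal_seqs, _ = augment_balance(split.train, src.genome, seed=seed)
train = encode_dataset(bal_seqs, [r.label for r in bal_recs], vocab)
val = encode_dataset([src.sequences[index[id(r)]] for r in split.validation],
                     [r.label for r in split.validation], vocab)
target = encode_dataset(tgt.sequences, tgt.labels, vocab)
L = train.ids.shape[1]


def fresh():
    return EPIModel(ModelConfig.desk_scale(max_positions=L), seed=seed,
                    vocab_hash=vocab.content_hash())


base, _ = finetune(train, val, fresh(), vocab, epochs=2, batch_size=16,
                   lr=1e-3, seed=seed)
a0 = classification_metrics(target.labels, predict_probs(base, target.ids))["auroc"]
print(f"source-only model, target AUROC {a0:.3f}")

dann, losses, _ = train_dann(train, val, target.ids, fresh(), vocab,
                             TransferConfig(lam=0.1), epochs=2, batch_size=8,
                             lr=1e-3, seed=seed)
a1 = classification_metrics(target.labels, predict_probs(dann, target.ids))["auroc"]
print(f"DANN model, target AUROC {a1:.3f} "
      f"(final L_class {losses[-1].l_class:.3f}, L_domain {losses[-1].l_domain:.3f})")
# target labels are used for evaluation only; training saw them unlabeled
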