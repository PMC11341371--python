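"""Attention-based de novo motif discovery on a trained classifier.

Trains a small model on a planted benchmark, calls high-attention regions
on the positive pairs, tests candidate subsequences for enrichment with
the hypergeometric upper tail, and merges the survivors into PWMs.  The
planted consensi — or, at this small scale, large fragments of them —
surface as the top motifs; at the full benchmark scale used by
scripts/acceptance.py the recovered consensi match the plants exactly.
"""

from epiattn import (ModelConfig, EPIModel, SynthSpec, Vocabulary,
                     augment_balance, encode_dataset, finetune,
                     generate_epi_dataset, split_dataset)
from epiattn import attention as attn

spec = SynthSpec(n_pos=100, n_neg=600, enh_len=240, prom_len=160,
                 mutation_rate=0.05, plant_prob=0.9, seed=3)
ds = generate_epi_dataset(spec)
vocab = Vocabulary()
split = split_dataset(ds.records, (0.8, 0.1, 0.1), seed=3)
index = {id(r): i for i, r in enumerate(ds.records)}
bal_recs, bal_seqs, _ = augment_balance(split.train, ds.genome, seed=3)
train = encode_dataset(bal_seqs, [r.label for r in bal_recs], vocab)
val = encode_dataset([ds.sequences[index[id(r)]] for r in split.validation],
                     [r.label for r in split.validation], vocab)
model = EPIModel(ModelConfig.desk_scale(max_positions=train.ids.shape[1]),
                 seed=3, vocab_hash=vocab.content_hash())
model, trace = finetune(train, val, model, vocab, epochs=2, batch_size=16,
                        lr=1e-3, seed=3)
print(f"classifier validation AUROC {max(t['auroc'] for t in trace):.3f}")

pos_idx = [i for i, r in enumerate(ds.records) if r.label == 1]
regions = attn.extract_high_attention_regions(
    model, [ds.sequences[i] for i in pos_idx], vocab)
for r in regions:
    r.record = pos_idx[r.record]
print(f"{len(regions)} high-attention regions on {len(pos_idx)} positives")

pwms, table = attn.discover_motifs(regions, ds.sequences, ds.labels,
                                   p_cutoff=0.005)
print(f"{len(pwms)} motifs after enrichment filtering and merging "
      f"(planted: {spec.enh_motif}, {spec.prom_motif})")
for p in pwms[:5]:
    print(f"  {p.consensus:>14s}  support {p.support:3d}  p {p.p_value:.2e}")
print(attn.export_meme(pwms[:1]))
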