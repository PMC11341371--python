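"""Generate a planted-motif EPI benchmark and inspect its ground truth.

Positives carry a mutated copy of an enhancer motif and a promoter motif;
negatives are pure background; negatives heavily outnumber positives, as
in real EPI benchmark collections.
"""

from epiattn import SynthSpec, generate_epi_dataset
from epiattn.training import augment_balance

spec = SynthSpec(n_pos=50, n_neg=500, enh_len=300, prom_len=200,
                 plant_prob=0.9, mutation_rate=0.05, seed=7)
ds = generate_epi_dataset(spec)
print(f"{len(ds.records)} records: {int(ds.labels.sum())} positive, "
      f"{int((1 - ds.labels).sum())} negative")
planted = ds.truth[ds.truth.enh_motif != ""]
print(f"{len(planted)} positives carry the enhancer motif {spec.enh_motif}")
row = planted.iloc[0]
enh = ds.sequences[row.record][0]
print(f"example: record {row.record}, planted copy {row.enh_copy!r} "
      f"at offset {row.enh_pos}; sequence context "
      f"...{enh[row.enh_pos-5:row.enh_pos+13]}...")

recs, seqs, prov = augment_balance(ds.records, ds.genome, shift_bound=50, seed=7)
labels = [r.label for r in recs]
print(f"after balancing: {sum(labels)} positive / {len(labels)-sum(labels)} "
      f"negative ({len(recs)-len(ds.records)} window-shifted copies)")
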