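"""Overlapping k-mer tokenization and paired-input assembly.

A DNA sequence of length L yields L-k+1 overlapping k-mers at stride 1
(k=6 by default).  A classification input is assembled as

    [CLS] enhancer 6-mers [SEP] promoter 6-mers

so a 3,000-bp enhancer plus a 2,000-bp promoter gives 4,992 positions:
CLS at 0, enhancer tokens at 1..2,995, SEP at 2,996, promoter tokens at
2,997..4,991.  k-mers containing non-ACGT bases map to UNK.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SPECIALS = ("PAD", "UNK", "CLS", "SEP", "MASK")

# per-position segment roles
ROLE_CLS, ROLE_ENH, ROLE_SEP, ROLE_PROM = 0, 1, 2, 3
ROLE_NAMES = {ROLE_CLS: "CLS", ROLE_ENH: "ENH", ROLE_SEP: "SEP", ROLE_PROM: "PROM"}


@dataclasses.dataclass(frozen=True)
class TokenizerConfig:
    k: int = 6
    specials: tuple[str, ...] = SPECIALS

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def vocab_size(self) -> int:
        return 4**self.k + len(self.specials)


class Vocabulary:
    """Bijective k-mer <-> id mapping: specials first, then lexicographic k-mers."""

    def __init__(self, config: TokenizerConfig = TokenizerConfig()):
        self.config = config
        self.k = config.k
        tokens = list(config.specials) + [
            "".join(p) for p in itertools.product("ACGT", repeat=config.k)
        ]
        self.token_to_id = {t: i for i, t in enumerate(tokens)}
        self.id_to_token = tokens
        for name in config.specials:
            setattr(self, f"{name.lower()}_id", self.token_to_id[name])

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode_kmer(self, kmer: str) -> int:
        return self.token_to_id.get(kmer, self.unk_id)

    def decode_id(self, idx: int) -> str:
        return self.id_to_token[idx]

    @property
    def n_specials(self) -> int:
        return len(self.config.specials)

    def is_special(self, idx: int) -> bool:
        return idx < self.n_specials

    def content_hash(self) -> str:
        """Stable hash tying checkpoints to the vocabulary that produced them."""
        h = hashlib.sha256("\n".join(self.id_to_token).encode())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, tok in enumerate(self.id_to_token):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = []
        with open(path) as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                assert int(idx) == len(tokens), "vocabulary file ids must be dense"
                tokens.append(tok)
        n_special = sum(1 for t in tokens if t in SPECIALS)
        k = len(tokens[n_special])
        vocab = cls(TokenizerConfig(k=k, specials=tuple(tokens[:n_special])))
        if vocab.id_to_token != tokens:
            raise ValueError("vocabulary file does not match canonical ordering")
        return vocab


def build_vocab(config: TokenizerConfig = TokenizerConfig()) -> Vocabulary:
    return Vocabulary(config)


def kmerize(seq: str, k: int = 6) -> list[str]:
    """All overlapping k-mers of ``seq`` in order (stride 1)."""
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


@dataclasses.dataclass
class TokenSequence:
    """Assembled CLS + enhancer + SEP + promoter token ids with segment roles."""

    ids: np.ndarray     # int64, shape (L,)
    roles: np.ndarray   # int8, shape (L,)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.roles = np.asarray(self.roles, dtype=np.int8)
        if self.ids.shape != self.roles.shape:
            raise ValueError("ids and roles must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def sep_index(self) -> int:
        return int(np.flatnonzero(self.roles == ROLE_SEP)[0])

    @property
    def enhancer_slice(self) -> slice:
        return slice(1, self.sep_index)

    @property
    def promoter_slice(self) -> slice:
        return slice(self.sep_index + 1, len(self.ids))


def assemble_pair(enh_seq: str, prom_seq: str, vocab: Vocabulary) -> TokenSequence:
    """Tokenize an enhancer/promoter pair into one classification input."""
    k = vocab.k
    enh_ids = [vocab.encode_kmer(m) for m in kmerize(enh_seq, k)]
    prom_ids = [vocab.encode_kmer(m) for m in kmerize(prom_seq, k)]
    ids = [vocab.cls_id] + enh_ids + [vocab.sep_id] + prom_ids
    roles = (
        [ROLE_CLS] + [ROLE_ENH] * len(enh_ids) + [ROLE_SEP] + [ROLE_PROM] * len(prom_ids)
    )
    return TokenSequence(np.array(ids), np.array(roles))


def _decode_segment(ids: Sequence[int], vocab: Vocabulary) -> str:
    kmers = []
    for idx in ids:
        if vocab.is_special(int(idx)):
            raise ValueError("cannot decode special/UNK tokens back to DNA")
        kmers.append(vocab.decode_id(int(idx)))
    k = vocab.k
    for a, b in zip(kmers, kmers[1:]):
        if a[1:] != b[:-1]:
            raise ValueError(f"inconsistent k-mer overlap: {a!r} -> {b!r}")
    return "".join(m[0] for m in kmers[:-1]) + kmers[-1]


def decode(tokens: TokenSequence, vocab: Vocabulary) -> tuple[str, str]:
    """Invert :func:`assemble_pair` for UNK-free inputs.

    Reconstruction takes the first base of each k-mer plus the full final
    k-mer per segment, and verifies overlap consistency.
    """
    enh = _decode_segment(tokens.ids[tokens.enhancer_slice], vocab)
    prom = _decode_segment(tokens.ids[tokens.promoter_slice], vocab)
    return enh, prom


def assemble_batch(
    pairs: Iterable[tuple[str, str]], vocab: Vocabulary
) -> list[TokenSequence]:
    return [assemble_pair(e, p, vocab) for e, p in pairs]
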