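"""Character-level tokenization of CDR3 sequences with aligned gene features.

Each amino acid is one token (20-letter vocabulary plus [PAD], [CLS], [SEP],
[UNK] specials).  The autoencoder layout is ``[CLS] residues [SEP] PAD...``
with the pooled representation read from the first position; the
autoregressive layout is ``residues [SEP] [CLS] PAD...`` with pooling at the
last non-padding position, following the XLNet convention.

V/J gene ordinals are broadcast across residue positions only: special tokens
and padding keep gene id 0 (the gene-embedding padding index), so a gene
embedding attaches to the protein sequence and never to special tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .vdjdb_io import AMINO_ACIDS

PAD, CLS, SEP, UNK = "[PAD]", "[CLS]", "[SEP]", "[UNK]"
SPECIAL_TOKENS = (PAD, CLS, SEP, UNK)


@dataclass(frozen=True)
class TokenizerSpec:
    """Vocabulary and layout settings.

    family 'autoencoder' puts the pooled [CLS] token first; 'autoregressive'
    puts it last, after the [SEP].
    """

    max_length: int = 32
    family: str = "autoencoder"
    tokens: tuple[str, ...] = SPECIAL_TOKENS + tuple(AMINO_ACIDS)

    def __post_init__(self):
        if self.family not in ("autoencoder", "autoregressive"):
            raise ValueError(f"unknown family {self.family!r}")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("token list has duplicates")

    @property
    def token_to_id(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    @property
    def pad_id(self) -> int:
        return self.tokens.index(PAD)

    @property
    def vocab_size(self) -> int:
        return len(self.tokens)

    @property
    def num_specials_in_layout(self) -> int:
        return 2  # CLS and SEP

    @classmethod
    def from_vocab_file(cls, path, **kwargs) -> "TokenizerSpec":
        with open(path) as fh:
            tokens = tuple(line.rstrip("\n") for line in fh if line.strip())
        return cls(tokens=tokens, **kwargs)


@dataclass
class TokenizedExample:
    """One model-ready sequence with aligned per-position gene features."""

    token_ids: np.ndarray
    attention_mask: np.ndarray
    segment_ids: np.ndarray
    v_feature_ids: np.ndarray
    j_feature_ids: np.ndarray
    label_id: int = -1
    n_unknown: int = 0
    residue_mask: np.ndarray = field(default=None)  # 1 at amino-acid positions


class OverLengthError(ValueError):
    pass


def tokenize(cdr3: str, spec: TokenizerSpec, label_id: int = -1) -> TokenizedExample:
    """Encode one CDR3 string; gene feature ids are zeroed (attach later)."""
    if not cdr3:
        raise ValueError("empty CDR3 sequence")
    if len(cdr3) > spec.max_length - spec.num_specials_in_layout:
        raise OverLengthError(
            f"CDR3 of length {len(cdr3)} exceeds max_length {spec.max_length} "
            f"minus {spec.num_specials_in_layout} special tokens")
    t2i = spec.token_to_id
    unk_id = t2i[UNK]
    residues = [t2i.get(aa, unk_id) for aa in cdr3]
    n_unknown = sum(1 for r in residues if r == unk_id)
    if spec.family == "autoencoder":
        body = [t2i[CLS]] + residues + [t2i[SEP]]
        res_positions = range(1, 1 + len(residues))
    else:  # autoregressive: pooled token last
        body = residues + [t2i[SEP]] + [t2i[CLS]]
        res_positions = range(0, len(residues))
    L = spec.max_length
    token_ids = np.full(L, spec.pad_id, dtype=np.intp)
    token_ids[: len(body)] = body
    mask = np.zeros(L, dtype=np.intp)
    mask[: len(body)] = 1
    residue_mask = np.zeros(L, dtype=np.intp)
    residue_mask[list(res_positions)] = 1
    return TokenizedExample(
        token_ids=token_ids,
        attention_mask=mask,
        segment_ids=np.zeros(L, dtype=np.intp),
        v_feature_ids=np.zeros(L, dtype=np.intp),
        j_feature_ids=np.zeros(L, dtype=np.intp),
        label_id=label_id,
        n_unknown=n_unknown,
        residue_mask=residue_mask,
    )


def detokenize(example: TokenizedExample, spec: TokenizerSpec) -> str:
    """Recover the CDR3 string from the residue positions."""
    return "".join(spec.tokens[i] for i, m in
                   zip(example.token_ids, example.residue_mask) if m)


def attach_gene_features(example: TokenizedExample, v_ordinal: int,
                         j_ordinal: int) -> TokenizedExample:
    """Broadcast V/J ordinals over residue positions; 0 everywhere else.

    Ordinal 0 is reserved as the gene padding index, so ordinals must be >= 1.
    Idempotent for fixed ordinals.
    """
    if v_ordinal < 1 or j_ordinal < 1:
        raise ValueError("gene ordinals must be >= 1 (0 is the padding index)")
    v_ids = example.residue_mask * int(v_ordinal)
    j_ids = example.residue_mask * int(j_ordinal)
    return replace(example, v_feature_ids=v_ids.astype(np.intp),
                   j_feature_ids=j_ids.astype(np.intp))


def write_vocab_file(spec: TokenizerSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(spec.tokens) + "\n")
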