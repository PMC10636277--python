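"""Reading and preparing VDJdb-dialect TCR-epitope tables.

The preparation cascade mirrors the standard curation of a VDJdb export for
multi-class specificity modelling: drop rows with missing mandatory values,
keep human/murine hosts, keep wet-lab-validated pairs (confidence score > 0),
drop epitope species of non-infectious origin, deduplicate on
(CDR3, V, J, MHC A, MHC B), keep TRB chains, and finally keep only epitope
classes with at least 50 receptors.  Each step is accounted for in a
:class:`FilterReport` so the shrinking dataset can be audited.

Class labels are the space-joined triple (epitope species, epitope parent
gene, epitope sequence), e.g. ``"MCMV m139 TVYGFCLL"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class Chain(str, Enum):
    TRA = "TRA"
    TRB = "TRB"


class MHCClass(str, Enum):
    MHCI = "MHCI"
    MHCII = "MHCII"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TCRRecord:
    """One receptor-epitope observation."""

    cdr3: str
    chain: Chain
    v_gene: str
    j_gene: str
    mhc_a: str
    mhc_b: str
    mhc_class: MHCClass
    host_species: str
    epitope_seq: str
    epitope_gene: str
    epitope_species: str
    confidence_score: int

    def __post_init__(self):
        if not self.cdr3 or not set(self.cdr3) <= _AA_SET:
            raise ValueError(f"cdr3 {self.cdr3!r} is not a canonical amino-acid string")
        if self.confidence_score not in (0, 1, 2, 3):
            raise ValueError(f"confidence_score {self.confidence_score!r} not in 0..3")


@dataclass(frozen=True)
class ClassLabel:
    """Composite epitope class label: species, parent gene, sequence."""

    epitope_species: str
    epitope_gene: str
    epitope_seq: str

    @property
    def parts(self) -> tuple[str, str, str]:
        return (self.epitope_species, self.epitope_gene, self.epitope_seq)

    @property
    def value(self) -> str:
        return " ".join(self.parts)

    def __str__(self) -> str:
        return self.value


@dataclass
class FilterReport:
    """Ordered per-step accounting of how many pairs remain."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][1]:
            raise ValueError("filter report counts must be non-increasing")
        self.steps.append((name, int(remaining)))

    def to_json(self) -> str:
        return json.dumps({"steps": [{"step": s, "remaining": r} for s, r in self.steps]},
                          indent=2)


@dataclass
class ParseError:
    row: int
    message: str


@dataclass
class ParseResult(Sequence):
    """Parsed records plus row-level rejections (bad score, bad CDR3...)."""

    records: list[TCRRecord]
    errors: list[ParseError]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[TCRRecord]:
        return iter(self.records)


# Default column names of a VDJdb web export.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "chain": "gene",
    "cdr3": "cdr3",
    "v_gene": "v.segm",
    "j_gene": "j.segm",
    "mhc_a": "mhc.a",
    "mhc_b": "mhc.b",
    "mhc_class": "mhc.class",
    "host_species": "species",
    "epitope_seq": "antigen.epitope",
    "epitope_gene": "antigen.gene",
    "epitope_species": "antigen.species",
    "confidence_score": "vdjdb.score",
}

MANDATORY_FIELDS = ("cdr3", "v_gene", "j_gene", "epitope_seq", "epitope_gene",
                    "epitope_species", "confidence_score")


class ColumnConfigurationError(KeyError):
    """A mandatory column is absent from the table or the column map."""


def read_vdjdb_table(source, column_map: Mapping[str, str] | None = None) -> ParseResult:
    """Read a tab-separated VDJdb-dialect table into records.

    `source` is a path or text stream.  `column_map` maps TCRRecord field
    names to column headers; fields mapped to None are treated as absent and
    filled with neutral defaults (except mandatory fields, which must be
    present).  Rows with an unparseable confidence score or a non-canonical
    CDR3 are collected in the error list instead of raising.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for fld in MANDATORY_FIELDS:
        col = cmap.get(fld)
        if col is None or col not in df.columns:
            raise ColumnConfigurationError(
                f"mandatory column for field {fld!r} (expected header {col!r}) is missing")

    records: list[TCRRecord] = []
    errors: list[ParseError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))

        def get(fld: str, default: str = "") -> str:
            col = cmap.get(fld)
            if col is None or col not in row:
                return default
            return str(row[col]).strip()

        score_raw = get("confidence_score")
        try:
            score = int(score_raw)
        except ValueError:
            errors.append(ParseError(i, f"unparseable confidence score {score_raw!r}"))
            continue
        mhc_raw = get("mhc_class")
        mhc_class = MHCClass(mhc_raw) if mhc_raw in ("MHCI", "MHCII") else MHCClass.UNKNOWN
        chain_raw = get("chain", "TRB").upper()
        chain = Chain(chain_raw) if chain_raw in ("TRA", "TRB") else None
        if chain is None:
            errors.append(ParseError(i, f"unknown chain {chain_raw!r}"))
            continue
        try:
            rec = TCRRecord(
                cdr3=get("cdr3").upper(),
                chain=chain,
                v_gene=get("v_gene"),
                j_gene=get("j_gene"),
                mhc_a=get("mhc_a"),
                mhc_b=get("mhc_b"),
                mhc_class=mhc_class,
                host_species=get("host_species"),
                epitope_seq=get("epitope_seq"),
                epitope_gene=get("epitope_gene"),
                epitope_species=get("epitope_species"),
                confidence_score=score,
            )
        except ValueError as e:
            errors.append(ParseError(i, str(e)))
            continue
        records.append(rec)
    return ParseResult(records, errors)


def records_to_frame(records: Iterable[TCRRecord],
                     column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Serialize records back to the VDJdb dialect."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rows = []
    for r in records:
        rows.append({
            cmap["chain"]: r.chain.value,
            cmap["cdr3"]: r.cdr3,
            cmap["v_gene"]: r.v_gene,
            cmap["j_gene"]: r.j_gene,
            cmap["mhc_a"]: r.mhc_a,
            cmap["mhc_b"]: r.mhc_b,
            cmap["mhc_class"]: r.mhc_class.value if r.mhc_class != MHCClass.UNKNOWN else "",
            cmap["host_species"]: r.host_species,
            cmap["epitope_seq"]: r.epitope_seq,
            cmap["epitope_gene"]: r.epitope_gene,
            cmap["epitope_species"]: r.epitope_species,
            cmap["confidence_score"]: r.confidence_score,
        })
    return pd.DataFrame(rows, columns=[cmap[k] for k in DEFAULT_COLUMN_MAP])


# ----------------------------------------------------------------------
# Filter cascade
# ----------------------------------------------------------------------

# Epitope species removed by default: self/tumour antigens, synthetic
# constructs, bacterial antigens and allergens.  The database does not pin
# these down to a closed set, so the list is configuration.
DEFAULT_EPITOPE_SPECIES_DENYLIST = (
    "HomoSapiens",        # autoimmune / cancer self-antigens
    "MusMusculus",        # murine self-antigens
    "synthetic",
    "Synthetic",
    "M.tuberculosis",     # bacterial
    "MycobacteriumTuberculosis",
    "TriticumAestivum",   # wheat gliadin (celiac / allergy)
)

DEFAULT_HOST_ALLOWLIST = ("HomoSapiens", "MusMusculus")

# Step names follow the published accounting of the cascade.
STEP_RAW = "Raw data"
STEP_NA = "Post removing N/A"
STEP_HOST = "Selecting only human and murine antigen"
STEP_SCORE = "Selecting TCR-epitope pairs with confidence score >0"
STEP_DENYLIST = "Post removing allergen and cancer antigen"
STEP_DEDUP = "Post removing duplicated entries"
STEP_TRB = "Selecting the TCR-epitope pairs with TRB sequences"
STEP_MIN_CLASS = "Selecting the TCR-epitope pairs with >=50 instances"


@dataclass
class FilterConfig:
    host_allowlist: tuple[str, ...] = DEFAULT_HOST_ALLOWLIST
    epitope_species_denylist: tuple[str, ...] = DEFAULT_EPITOPE_SPECIES_DENYLIST
    min_score: int = 0          # exclusive bound: keep score > min_score
    min_class_size: int = 50


def _has_mandatory_values(r: TCRRecord) -> bool:
    return all(getattr(r, f) != "" for f in
               ("cdr3", "v_gene", "j_gene", "epitope_seq", "epitope_gene",
                "epitope_species"))


def deduplicate(records: Sequence[TCRRecord]) -> list[TCRRecord]:
    """Keep the first occurrence of each (cdr3, v, j, mhc_a, mhc_b) key.

    Order-preserving and idempotent.
    """
    seen: set[tuple] = set()
    out: list[TCRRecord] = []
    for r in records:
        key = (r.cdr3, r.v_gene, r.j_gene, r.mhc_a, r.mhc_b)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def apply_filters(records: Sequence[TCRRecord],
                  config: FilterConfig | None = None
                  ) -> tuple[list[TCRRecord], FilterReport]:
    """Run the row-level cascade (everything before the class-size cut)."""
    config = config or FilterConfig()
    report = FilterReport()
    cur = list(records)
    report.add(STEP_RAW, len(cur))

    cur = [r for r in cur if _has_mandatory_values(r)]
    report.add(STEP_NA, len(cur))

    allow = set(config.host_allowlist)
    cur = [r for r in cur if r.host_species in allow]
    report.add(STEP_HOST, len(cur))

    cur = [r for r in cur if r.confidence_score > config.min_score]
    report.add(STEP_SCORE, len(cur))

    deny = set(config.epitope_species_denylist)
    cur = [r for r in cur if r.epitope_species not in deny]
    report.add(STEP_DENYLIST, len(cur))

    cur = deduplicate(cur)
    report.add(STEP_DEDUP, len(cur))

    cur = [r for r in cur if r.chain == Chain.TRB]
    report.add(STEP_TRB, len(cur))
    return cur, report


def assign_class_labels(records: Sequence[TCRRecord]
                        ) -> list[tuple[TCRRecord, ClassLabel]]:
    """Label each record with its (species, gene, sequence) epitope triple."""
    out = []
    for r in records:
        if not (r.epitope_species and r.epitope_gene and r.epitope_seq):
            raise ValueError(f"record {r.cdr3} has an empty epitope field")
        out.append((r, ClassLabel(r.epitope_species, r.epitope_gene, r.epitope_seq)))
    return out


def min_class_size_filter(labelled: Sequence[tuple[TCRRecord, ClassLabel]],
                          min_n: int = 50) -> list[tuple[TCRRecord, ClassLabel]]:
    """Keep only classes with at least `min_n` members (inclusive bound)."""
    counts: dict[str, int] = {}
    for _, lab in labelled:
        counts[lab.value] = counts.get(lab.value, 0) + 1
    return [(r, lab) for r, lab in labelled if counts[lab.value] >= min_n]


def categorize_difficulty(class_counts: Mapping[str, int]) -> dict[str, str]:
    """Classes with more than 100 instances are easy; 100 or fewer are hard."""
    out = {}
    for label, count in class_counts.items():
        if count <= 0:
            raise ValueError(f"class {label!r} has non-positive count {count}")
        out[label] = "easy" if count > 100 else "hard"
    return out


# ----------------------------------------------------------------------
# Gene vocabulary and splits
# ----------------------------------------------------------------------

@dataclass
class GeneVocabulary:
    """Ordinal encoder for gene names.

    Ordinals start at 1; index 0 is reserved for padding ("no gene") and the
    last slot is a special index for names unseen at fit time.  The embedding
    table size is therefore n_names + 2.
    """

    names: list[str]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("gene names must be unique")
        self.index_of = {name: i + 1 for i, name in enumerate(self.names)}

    @property
    def padding_index(self) -> int:
        return 0

    @property
    def special_index(self) -> int:
        return len(self.names) + 1

    @property
    def table_size(self) -> int:
        return len(self.names) + 2

    def encode(self, name: str) -> int:
        return self.index_of.get(name, self.special_index)

    def decode(self, ordinal: int) -> str:
        if 1 <= ordinal <= len(self.names):
            return self.names[ordinal - 1]
        raise KeyError(f"ordinal {ordinal} has no gene name")

    def to_json(self) -> str:
        return json.dumps({"names": self.names, "padding_index": 0,
                           "special_index": self.special_index,
                           "table_size": self.table_size})

    @classmethod
    def from_json(cls, s: str) -> "GeneVocabulary":
        return cls(names=json.loads(s)["names"])


def build_gene_vocabulary(records: Sequence[TCRRecord], field: str) -> GeneVocabulary:
    """Ordinal vocabulary over the unique values of `field` (lexicographic)."""
    if field not in ("v_gene", "j_gene"):
        raise ValueError("field must be 'v_gene' or 'j_gene'")
    names = sorted({getattr(r, field) for r in records})
    if any(n == "" for n in names):
        raise ValueError("empty gene name encountered")
    return GeneVocabulary(names=names)


@dataclass
class SplitAssignment:
    """Stratified 70/15/15 partition of record ids."""

    partition: dict[int, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> list[int]:
        return [i for i, p in self.partition.items() if p == part]

    def to_json(self) -> str:
        return json.dumps({"fractions": self.fractions, "seed": self.seed,
                           "partition": {str(k): v for k, v in self.partition.items()}})


def stratified_split(labels: Sequence[str],
                     fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                     seed: int = 0) -> SplitAssignment:
    """Per-class split: train floor(f_train*n), val floor(f_val*n), rest test.

    `labels` is the class label of record i at position i.  Within a class the
    assignment is a seeded uniform shuffle, so a fixed seed gives an identical
    partition.  Classes smaller than 3 cannot populate three partitions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab, idx in by_class.items():
        if len(idx) < 3:
            raise ValueError(f"class {lab!r} has fewer than 3 members")
    rng = np.random.default_rng(seed)
    partition: dict[int, str] = {}
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(np.floor(fractions[0] * n))
        n_val = int(np.floor(fractions[1] * n))
        for i in idx[:n_train]:
            partition[int(i)] = "train"
        for i in idx[n_train:n_train + n_val]:
            partition[int(i)] = "validation"
        for i in idx[n_train + n_val:]:
            partition[int(i)] = "test"
    return SplitAssignment(partition=partition, fractions=tuple(fractions), seed=seed)


def prepare(records: Sequence[TCRRecord],
            config: FilterConfig | None = None,
            seed: int = 0) -> dict:
    """Full preparation pipeline: cascade, labels, class-size cut, vocabularies,
    difficulty map and stratified split.  Returns a dict of artefacts."""
    config = config or FilterConfig()
    retained, report = apply_filters(records, config)
    labelled = assign_class_labels(retained)
    labelled = min_class_size_filter(labelled, config.min_class_size)
    report.add(STEP_MIN_CLASS, len(labelled))
    recs = [r for r, _ in labelled]
    labels = [lab.value for _, lab in labelled]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    artefacts = {
        "records": recs,
        "labels": labels,
        "report": report,
        "class_counts": counts,
        "difficulty": categorize_difficulty(counts) if counts else {},
        "v_vocab": build_gene_vocabulary(recs, "v_gene") if recs else None,
        "j_vocab": build_gene_vocabulary(recs, "j_gene") if recs else None,
        "split": stratified_split(labels, seed=seed) if recs else None,
    }
    return artefacts
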