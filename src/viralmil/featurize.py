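"""Fixed-length instance features: k-mer composition vectors and an adapter
for externally computed protein embeddings.

Three k-mer schemes are supported, chosen so the feature dimension stays
manageable for the bag classifier:

* ``DNA_5`` — 5-mers over A/C/G/T on CDS nucleotides (dim 1024),
* ``AA_2``  — 2-mers over the 20 amino acids (dim 400),
* ``PC_3``  — 3-mers over a 7-letter physiochemical residue alphabet
  (dim 343), where residues are first pooled into the groups
  AGV | C | FILP | MSTY | HNQW | DE | KR.

Every k-mer vector is normalized to sum to 1 so sequence length does not
dominate the representation. Windows containing symbols outside the scheme
alphabet (ambiguity codes such as N or X) are skipped rather than the whole
sequence being rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .bags import VirusBag

__all__ = [
    "KmerScheme",
    "EmbeddingTable",
    "DegenerateSequenceError",
    "PC_GROUPS",
    "EMBEDDING_DIM",
    "DNA_5",
    "AA_2",
    "PC_3",
    "get_scheme",
    "pc_recode",
    "kmer_vector",
    "featurize_bag",
    "write_feature_matrix",
]

#: embedding adapter dimension (mean-pooled per-fragment representations)
EMBEDDING_DIM = 1280

#: the 7 physiochemical residue groups, in their canonical printed order
PC_GROUPS: tuple[str, ...] = ("AGV", "C", "FILP", "MSTY", "HNQW", "DE", "KR")

#: group symbols '0'..'6' in the order of PC_GROUPS
_PC_SYMBOLS = "0123456"
_PC_MAP = {res: _PC_SYMBOLS[i] for i, grp in enumerate(PC_GROUPS) for res in grp}
_PC_UNKNOWN = "?"


class DegenerateSequenceError(ValueError):
    """Raised when a sequence yields no valid k-mer window."""


@dataclass(frozen=True)
class KmerScheme:
    """One k-mer featurizer: an ordered alphabet, k, optional residue recoding."""

    name: str
    alphabet: str
    k: int
    recode: bool = False  # apply pc_recode before counting
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        kmers = ["".join(p) for p in product(self.alphabet, repeat=self.k)]
        object.__setattr__(self, "_index", {km: i for i, km in enumerate(kmers)})

    @property
    def dim(self) -> int:
        return len(self.alphabet) ** self.k

    def kmer_order(self) -> list[str]:
        """k-mers in vector-index order (lexicographic over the alphabet)."""
        return ["".join(p) for p in product(self.alphabet, repeat=self.k)]


DNA_5 = KmerScheme("DNA_5", "ACGT", 5)
AA_2 = KmerScheme("AA_2", "ACDEFGHIKLMNPQRSTVWY", 2)
PC_3 = KmerScheme("PC_3", _PC_SYMBOLS, 3, recode=True)

_SCHEMES = {"DNA_5": DNA_5, "AA_2": AA_2, "PC_3": PC_3}


def get_scheme(name: str) -> KmerScheme:
    """Look up a scheme by name (case-insensitive, 'dna5'/'DNA_5' both work)."""
    key = name.upper().replace("-", "_")
    if "_" not in key:
        key = key[:-1] + "_" + key[-1]
    try:
        return _SCHEMES[key]
    except KeyError:
        raise KeyError(f"unknown k-mer scheme {name!r}; choose from {sorted(_SCHEMES)}") from None


def pc_recode(residues: str) -> str:
    """Recode amino acids into the 7-group physiochemical alphabet.

    Length is preserved; residues outside the 20 standard amino acids map to
    an unknown placeholder that no k-mer window will match.
    """
    return "".join(_PC_MAP.get(r, _PC_UNKNOWN) for r in residues.upper())


def kmer_vector(seq: str, scheme: KmerScheme) -> np.ndarray:
    """Normalized k-mer composition of ``seq`` under ``scheme``.

    Slides a width-k window with step 1, counts windows whose symbols all
    belong to the scheme alphabet, and divides by the total count so the
    vector sums to 1. Raises :class:`DegenerateSequenceError` when no valid
    window exists.
    """
    s = pc_recode(seq) if scheme.recode else seq.upper()
    k = scheme.k
    counts = np.zeros(scheme.dim, dtype=np.float64)
    index = scheme._index
    total = 0
    for i in range(len(s) - k + 1):
        j = index.get(s[i:i + k])
        if j is not None:
            counts[j] += 1
            total += 1
    if total == 0:
        raise DegenerateSequenceError(
            f"no valid {scheme.name} window of width {k} in sequence of length {len(seq)}"
        )
    return counts / total


@dataclass
class EmbeddingTable:
    """Adapter for externally computed per-fragment embedding vectors.

    Maps ``(virus_id, protein_id, fragment_index)`` to a 1280-d vector.
    The table validates dimension only; computing embeddings is out of
    scope for this package.
    """

    vectors: dict[tuple[str, str, int], np.ndarray] = field(default_factory=dict)
    dim: int = EMBEDDING_DIM

    def add(self, virus_id: str, protein_id: str, fragment_index: int, vec) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (self.dim,):
            raise ValueError(
                f"embedding for ({virus_id}, {protein_id}, {fragment_index}) has "
                f"shape {vec.shape}, expected ({self.dim},)"
            )
        self.vectors[(virus_id, protein_id, fragment_index)] = vec

    def __contains__(self, key) -> bool:
        return key in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def save(self, directory: str | Path) -> None:
        """Write one TSV matrix per virus plus a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        by_virus: dict[str, list] = {}
        for (vid, pid, fi), vec in self.vectors.items():
            by_virus.setdefault(vid, []).append((pid, fi, vec))
        manifest = {"dim": self.dim, "viruses": sorted(by_virus)}
        for vid, rows in by_virus.items():
            with open(directory / f"{vid}.tsv", "w") as fh:
                for pid, fi, vec in sorted(rows, key=lambda r: (r[0], r[1])):
                    fh.write(f"{pid}\t{fi}\t" + "\t".join(f"{v:.8g}" for v in vec) + "\n")
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingTable":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        table = cls(dim=int(manifest["dim"]))
        for vid in manifest["viruses"]:
            with open(directory / f"{vid}.tsv") as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    pid, fi = parts[0], int(parts[1])
                    vec = np.array(parts[2:], dtype=np.float64)
                    if vec.shape != (table.dim,):
                        raise ValueError(
                            f"{vid}.tsv row ({pid},{fi}) has {vec.size} columns, "
                            f"expected {table.dim}"
                        )
                    table.vectors[(vid, pid, fi)] = vec
        return table


def featurize_bag(bag: VirusBag, scheme_or_table: KmerScheme | EmbeddingTable) -> VirusBag:
    """Attach feature vectors to a raw-sequence bag skeleton.

    Returns a new bag with the same instances and label. Under a
    :class:`KmerScheme` each instance's sequence is counted; under an
    :class:`EmbeddingTable` vectors are looked up by provenance key, and a
    lookup error lists every absent instance.
    """
    if isinstance(scheme_or_table, EmbeddingTable):
        table = scheme_or_table
        missing = [
            (bag.virus_id, inst.protein_id, inst.fragment_index)
            for inst in bag.instances
            if (bag.virus_id, inst.protein_id, inst.fragment_index) not in table
        ]
        if missing:
            raise KeyError(f"embeddings missing for instances: {missing}")
        feats = np.stack([
            table.vectors[(bag.virus_id, inst.protein_id, inst.fragment_index)]
            for inst in bag.instances
        ])
    else:
        scheme = scheme_or_table
        rows = []
        for inst in bag.instances:
            if inst.sequence is None:
                raise ValueError(
                    f"instance ({inst.protein_id},{inst.fragment_index}) of bag "
                    f"{bag.virus_id!r} has no sequence to featurize"
                )
            try:
                rows.append(kmer_vector(inst.sequence, scheme))
            except DegenerateSequenceError as e:
                raise DegenerateSequenceError(
                    f"bag {bag.virus_id!r} instance ({inst.protein_id},"
                    f"{inst.fragment_index}): {e}"
                ) from None
        feats = np.stack(rows)
    return VirusBag(virus_id=bag.virus_id, instances=list(bag.instances),
                    features=feats, label=bag.label)


def write_feature_matrix(bags: list[VirusBag], path: str | Path, tag: str) -> None:
    """Export featurized bags as TSV with a header naming the featurizer."""
    with open(path, "w") as fh:
        dim = bags[0].dim if bags else 0
        fh.write("virus_id\tprotein_id\tfragment_index\t"
                 + "\t".join(f"{tag}_{i}" for i in range(dim)) + "\n")
        for bag in bags:
            for inst, row in zip(bag.instances, bag.features):
                fh.write(f"{bag.virus_id}\t{inst.protein_id}\t{inst.fragment_index}\t"
                         + "\t".join(f"{v:.8g}" for v in row) + "\n")
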