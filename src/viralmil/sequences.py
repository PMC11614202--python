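"""Reading and preparing viral sequences.

Protein sequences destined for a 1280-d language-model embedding must fit
the embedding model's 1022-token window, so long proteins are cut into
1022-residue fragments; a trailing fragment shorter than 25 residues is
discarded as uninformative. The ambiguity code 'J' (Leu-or-Ile) is resolved
by a seeded coin flip because downstream embedding vocabularies lack it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .bags import Instance, VirusBag

__all__ = [
    "ProteinRecord",
    "SequenceFragment",
    "CdsRecord",
    "FastaParseError",
    "MAX_FRAGMENT_LEN",
    "MIN_TAIL_LEN",
    "read_fasta",
    "sanitize_protein",
    "split_protein",
    "assemble_bag",
    "write_bag_skeleton",
]

#: longest sequence the embedding model accepts (1024 tokens minus BOS/EOS)
MAX_FRAGMENT_LEN = 1022
#: a trailing fragment shorter than this is discarded
MIN_TAIL_LEN = 25

# 20 standard residues plus ambiguity codes tolerated on input
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS_AA = set("BZXUO")
_DNA_OK = set("ACGTRYSWKMBDHVN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending record."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    virus_id: str
    residues: str
    description: str = ""


@dataclasses.dataclass(frozen=True)
class SequenceFragment:
    parent_protein_id: str
    fragment_index: int
    residues: str


@dataclasses.dataclass(frozen=True)
class CdsRecord:
    cds_id: str
    virus_id: str
    bases: str
    description: str = ""


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[ProteinRecord] | list[CdsRecord]:
    """Read a FASTA file into protein or CDS records.

    The virus id defaults to the record id; callers that key bags by a
    separate virus identifier reassign it when assembling bags. Sequences
    are uppercased; characters outside the accepted alphabet raise
    :class:`FastaParseError`.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"alphabet must be 'protein' or 'dna', got {alphabet!r}")
    path = Path(path)
    allowed = _STANDARD_AA | _AMBIGUOUS_AA | {"J", "*"} if alphabet == "protein" else _DNA_OK
    records: list = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
        bad = set(seq) - allowed
        if bad:
            raise FastaParseError(
                f"record {rec.id!r} in {path} contains characters {sorted(bad)} "
                f"outside the {alphabet} alphabet"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        if alphabet == "protein":
            records.append(ProteinRecord(protein_id=rec.id, virus_id=rec.id, residues=seq, description=desc))
        else:
            records.append(CdsRecord(cds_id=rec.id, virus_id=rec.id, bases=seq, description=desc))
    return records


def sanitize_protein(residues: str, rng_seed: int) -> str:
    """Resolve 'J' residues and strip a terminal stop symbol.

    Each 'J' is independently replaced by 'L' or 'I' with equal probability
    using a generator seeded with ``rng_seed``, so the substitution is
    reproducible. A single trailing ``*`` (translated stop) is removed.
    All other positions are untouched.
    """
    if not residues:
        raise ValueError("empty protein sequence")
    residues = residues.upper()
    if residues.endswith("*"):
        residues = residues[:-1]
        if not residues:
            raise ValueError("protein sequence is a bare stop symbol")
    if "J" in residues:
        rng = np.random.default_rng(rng_seed)
        chars = list(residues)
        for i, c in enumerate(chars):
            if c == "J":
                chars[i] = "L" if rng.random() < 0.5 else "I"
        residues = "".join(chars)
    bad = set(residues) - _STANDARD_AA - _AMBIGUOUS_AA
    if bad:
        raise ValueError(f"sequence contains invalid residues {sorted(bad)} after sanitation")
    return residues


def split_protein(residues: str, parent_protein_id: str = "") -> list[SequenceFragment]:
    """Cut a protein into fragments that fit the 1022-residue window.

    A protein shorter than ``1022 + 25`` residues yields a single fragment
    truncated to at most 1022 residues. Longer proteins are cut into
    consecutive 1022-residue fragments left to right; a final fragment is
    kept only if it has at least 25 residues. The retained fragments always
    reconstruct a prefix of the input.
    """
    n = len(residues)
    if n == 0:
        raise ValueError("cannot split an empty sequence")
    if n < MAX_FRAGMENT_LEN + MIN_TAIL_LEN:
        return [SequenceFragment(parent_protein_id, 0, residues[:MAX_FRAGMENT_LEN])]
    frags: list[SequenceFragment] = []
    for i, start in enumerate(range(0, n, MAX_FRAGMENT_LEN)):
        piece = residues[start:start + MAX_FRAGMENT_LEN]
        if len(piece) == MAX_FRAGMENT_LEN or len(piece) >= MIN_TAIL_LEN:
            frags.append(SequenceFragment(parent_protein_id, len(frags), piece))
    return frags


def assemble_bag(virus_id: str, records: Sequence[ProteinRecord | CdsRecord]) -> VirusBag:
    """Assemble one virus's records into a raw-sequence bag skeleton.

    Protein records are split first, each fragment becoming its own
    instance; CDS records map one-to-one onto instances. Input order is
    preserved.
    """
    if not records:
        raise ValueError(f"no records supplied for virus {virus_id!r}")
    mixed = {r.virus_id for r in records}
    if mixed != {virus_id}:
        raise ValueError(f"records carry virus ids {sorted(mixed)}, expected only {virus_id!r}")
    instances: list[Instance] = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            for frag in split_protein(rec.residues, rec.protein_id):
                instances.append(Instance(rec.protein_id, frag.fragment_index, frag.residues))
        else:
            instances.append(Instance(rec.cds_id, 0, rec.bases))
    return VirusBag(virus_id=virus_id, instances=instances)


def write_bag_skeleton(bags: Iterable[VirusBag], path: str | Path) -> None:
    """Serialize bag skeletons as TSV: virus_id, protein_id, fragment_index, sequence."""
    with open(path, "w") as fh:
        fh.write("virus_id\tprotein_id\tfragment_index\tsequence\n")
        for bag in bags:
            for inst in bag.instances:
                fh.write(f"{bag.virus_id}\t{inst.protein_id}\t{inst.fragment_index}\t{inst.sequence or ''}\n")
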