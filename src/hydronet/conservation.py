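"""Site conservation and designed-motif co-occurrence over an aligned family.

Operates on a pre-filtered multiple sequence alignment (for GPCRs, typically
all class-A receptors over the structurally conserved transmembrane helices,
pre-filtered upstream by similarity to the reference; that filter is input
provenance, not computed here).  Sites are addressed by generic residue
numbers (Ballesteros-Weinstein H.pos codes) through a column map built by
walking the gapped reference row.

By default gapped sequences are excluded from a column's denominator, the
standard convention for per-site conservation; set ``count_gaps=True`` to
keep them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .structure_io import BWAnnotation

GAP_CHARS = set("-.")


@dataclass
class MSA:
    sequences: list[tuple[str, str]]  # (id, aligned sequence)
    provenance: str = ""  # e.g. the upstream E-value filter applied

    def __post_init__(self) -> None:
        if self.sequences:
            L = len(self.sequences[0][1])
            if any(len(s) != L for _, s in self.sequences):
                raise ValueError("aligned sequences must share one length")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    def get(self, seq_id: str) -> str | None:
        for sid, s in self.sequences:
            if sid == seq_id:
                return s
        return None


def load_msa(path: str | Path, fmt: str | None = None, provenance: str = "") -> MSA:
    """Read an aligned FASTA or Stockholm file."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MSA(
        sequences=[(rec.id, str(rec.seq).upper()) for rec in aln],
        provenance=provenance,
    )


@dataclass
class SiteMap:
    """Generic residue code -> alignment column (0-based internally)."""

    columns: dict[str, int] = field(default_factory=dict)

    def column(self, bw_code: str) -> int:
        if bw_code not in self.columns:
            raise KeyError(f"site {bw_code} is not mapped")
        return self.columns[bw_code]


def map_columns(
    msa: MSA,
    reference_id: str,
    annotation: BWAnnotation,
    chain: str = "A",
    first_resnum: int = 1,
) -> SiteMap:
    """Map generic residue codes to alignment columns via the reference row.

    Walks the reference sequence, skipping gap columns; the k-th non-gap
    column corresponds to residue number ``first_resnum + k`` of ``chain``
    in the annotation, whose generic code (if any) is mapped to that column.
    The map is injective and only covers columns that are non-gap in the
    reference.
    """
    ref = msa.get(reference_id)
    if ref is None:
        raise ValueError(f"reference sequence {reference_id!r} not in alignment")
    columns: dict[str, int] = {}
    resnum = first_resnum
    for col, ch in enumerate(ref):
        if ch in GAP_CHARS:
            continue
        entry = annotation.lookup(chain, resnum)
        if entry is not None and entry.bw_code:
            if entry.bw_code in columns:
                raise ValueError(f"generic code {entry.bw_code} maps to two columns")
            columns[entry.bw_code] = col
        resnum += 1
    return SiteMap(columns=columns)


def site_conservation(
    msa: MSA,
    site_map: SiteMap,
    bw_code: str,
    residue: str,
    count_gaps: bool = False,
) -> float:
    """Fraction of sequences carrying ``residue`` at a mapped site.

    Gapped sequences are excluded from the denominator unless
    ``count_gaps`` is set.
    """
    col = site_map.column(bw_code)
    residue = residue.upper()
    hits = 0
    total = 0
    for _, seq in msa.sequences:
        ch = seq[col]
        if ch in GAP_CHARS:
            if count_gaps:
                total += 1
            continue
        total += 1
        if ch == residue:
            hits += 1
    if total == 0:
        raise ValueError(f"no ungapped sequences at site {bw_code}")
    return hits / total


def motif_cooccurrence(
    msa: MSA,
    site_map: SiteMap,
    design_mutations: list[tuple[str, str]],
    min_k: int = 2,
) -> tuple[int, list[str]]:
    """Sequences naturally carrying at least ``min_k`` designed residues.

    ``design_mutations`` lists (generic code, designed amino acid) pairs;
    returns the number of matching sequences and their ids.
    """
    if min_k < 1:
        raise ValueError("min_k must be >= 1")
    pairs = [(site_map.column(bw), aa.upper()) for bw, aa in design_mutations]
    matches = []
    for sid, seq in msa.sequences:
        k = sum(1 for col, aa in pairs if seq[col] == aa)
        if k >= min_k:
            matches.append(sid)
    return len(matches), matches


def conservation_report(
    msa: MSA,
    site_map: SiteMap,
    reference_id: str,
    designed: dict[str, str],
) -> list[dict]:
    """Per-site table: reference residue vs designed residue frequencies."""
    ref = msa.get(reference_id)
    if ref is None:
        raise ValueError(f"reference sequence {reference_id!r} not in alignment")
    rows = []
    for bw, designed_aa in designed.items():
        col = site_map.column(bw)
        ref_aa = ref[col]
        rows.append(
            {
                "bw_code": bw,
                "reference_aa": ref_aa,
                "designed_aa": designed_aa.upper(),
                "freq_reference": site_conservation(msa, site_map, bw, ref_aa),
                "freq_designed": site_conservation(msa, site_map, bw, designed_aa),
            }
        )
    return rows
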