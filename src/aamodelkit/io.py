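"""Alignment and tree file I/O (FASTA, relaxed PHYLIP, Newick)."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .likelihood import Alignment
from .trees import PhyloTree


def read_alignment(path, fmt: str = "auto") -> Alignment:
    """Read a protein alignment from FASTA or (relaxed) PHYLIP."""
    fmt = fmt.lower()
    if fmt == "auto":
        with open(path) as fh:
            first = fh.readline()
        fmt = "fasta" if first.startswith(">") else "phylip"
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences found")
        return Alignment([r.id for r in records], [str(r.seq) for r in records])
    if fmt == "phylip":
        return _read_relaxed_phylip(path)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _read_relaxed_phylip(path) -> Alignment:
    """Relaxed PHYLIP: header 'ntaxa nsites', then whitespace-delimited
    name + sequence per line (sequences may continue in interleaved blocks)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split()
    if len(header) < 2:
        raise ValueError(f"{path}: malformed PHYLIP header {lines[0]!r}")
    try:
        ntaxa, nsites = int(header[0]), int(header[1])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed PHYLIP header {lines[0]!r}") from exc
    body = lines[1:]
    if len(body) < ntaxa:
        raise ValueError(f"{path}: header declares {ntaxa} sequences, file has {len(body)}")
    labels, seqs = [], []
    for ln in body[:ntaxa]:
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}: cannot split name from sequence in line {ln!r}")
        labels.append(parts[0])
        seqs.append(parts[1].replace(" ", ""))
    # interleaved continuation blocks
    rest = body[ntaxa:]
    for i, ln in enumerate(rest):
        seqs[i % ntaxa] += ln.replace(" ", "")
    bad = [labels[i] for i, s in enumerate(seqs) if len(s) != nsites]
    if bad:
        raise ValueError(
            f"{path}: header declares {nsites} sites but sequences {bad} differ in length"
        )
    return Alignment(labels, seqs)


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    fmt = fmt.lower()
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(s), id=lbl, description="") for lbl, s in zip(aln.labels, aln.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {aln.n_sequences} {aln.n_sites}\n")
            for lbl, s in zip(aln.labels, aln.sequences):
                fh.write(f"{lbl}  {s}\n")
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")


def read_tree(path) -> PhyloTree:
    return PhyloTree.from_file(path)


def write_tree(tree: PhyloTree, path) -> None:
    tree.write(path)
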