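"""Readers and writers for the pipeline's plain-text formats.

FASTA goes through Biopython; contacts, allele tables, hits, counts and
grouping tables are TSV with ``#``-prefixed header comments carrying the
seed and config hash; unitig overlaps use the 12 mandatory PAF columns.
All writers round-trip: parse(write(x)) == x.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phasing import ContactMap, Grouping, OverlapRecord, OverlapSet


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_contacts(cmap: ContactMap, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("unitig_a\tunitig_b\tcount\n")
        for a, b, c in cmap.pairs():
            fh.write(f"{a}\t{b}\t{c}\n")


def write_lengths(lengths: dict[str, int], path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("unitig\tlength\n")
        for u in sorted(lengths):
            fh.write(f"{u}\t{lengths[u]}\n")


def read_contacts(contacts_path, lengths_path) -> ContactMap:
    lens = pd.read_csv(lengths_path, sep="\t", comment="#")
    contacts = pd.read_csv(contacts_path, sep="\t", comment="#")
    lengths = dict(zip(lens["unitig"], lens["length"].astype(int)))
    counts = {
        (a, b): int(c)
        for a, b, c in zip(
            contacts["unitig_a"], contacts["unitig_b"], contacts["count"]
        )
    }
    return ContactMap(lengths, counts)


PAF_COLUMNS = 12


def write_paf(overlaps: OverlapSet, path) -> None:
    with open(path, "w") as fh:
        for r in overlaps.records:
            fh.write(
                f"{r.query}\t{r.query_len}\t{r.query_start}\t{r.query_end}\t"
                f"{r.strand}\t{r.target}\t{r.target_len}\t{r.target_start}\t"
                f"{r.target_end}\t{r.n_match}\t{r.aln_len}\t{r.mapq}\n"
            )


def read_paf(path) -> OverlapSet:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < PAF_COLUMNS:
                raise ValueError(
                    f"{path}: line {ln}: {len(fields)} columns, "
                    f"PAF requires {PAF_COLUMNS}"
                )
            try:
                records.append(OverlapRecord(
                    query=fields[0], query_len=int(fields[1]),
                    query_start=int(fields[2]), query_end=int(fields[3]),
                    strand=fields[4],
                    target=fields[5], target_len=int(fields[6]),
                    target_start=int(fields[7]), target_end=int(fields[8]),
                    n_match=int(fields[9]), aln_len=int(fields[10]),
                    mapq=int(fields[11]),
                ))
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: {e}") from None
    return OverlapSet(records)


def write_allele_table(alleles: dict[str, set[str]], path,
                       meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("ref_gene\tunitigs\n")
        for gene in sorted(alleles):
            fh.write(f"{gene}\t{','.join(sorted(alleles[gene]))}\n")


def read_allele_table(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        row.ref_gene: set(str(row.unitigs).split(","))
        for row in df.itertuples(index=False)
    }


def write_grouping(grouping: Grouping, chrom: str, path,
                   meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("unitig\tchromosome\tgroup\tstatus\n")
        rows = []
        for gi, g in enumerate(grouping.groups):
            rows += [(u, chrom, gi, "grouped") for u in sorted(g)]
        rows += [(u, chrom, -1, "ungrouped") for u in sorted(grouping.ungrouped)]
        for u, c, gi, status in sorted(rows):
            fh.write(f"{u}\t{c}\t{gi}\t{status}\n")


def read_grouping(path) -> Grouping:
    df = pd.read_csv(path, sep="\t", comment="#")
    n_groups = int(df.loc[df["group"] >= 0, "group"].max()) + 1 if (df["group"] >= 0).any() else 0
    groups = [set() for _ in range(n_groups)]
    ungrouped = set()
    for row in df.itertuples(index=False):
        if row.status == "ungrouped":
            ungrouped.add(row.unitig)
        else:
            groups[int(row.group)].add(row.unitig)
    return Grouping(groups=groups, ungrouped=ungrouped)


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
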