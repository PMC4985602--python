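"""Readers and writers for the plain-text formats shared by all stages.

FASTA/FASTQ go through Biopython; tabular reports (difference/exclusion
tables, coverage tracks, truth manifests, topology and MIC tables) are
TSV/CSV via pandas; gene models round-trip through minimal GFF3; run
configuration through YAML.  All writers round-trip losslessly through
their readers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from bactarget.micassay import DilutionSeries
from bactarget.synthdata import ALL_STRAINS, GeneModel, MutationSpec, SimRead
from bactarget.topology import TopologyModel
from bactarget.varcall import DifferenceRecord


# --------------------------------------------------------------------- FASTA / FASTQ

def write_fasta(path: str | Path, contigs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: Iterable[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# --------------------------------------------------------------------- GFF3

def write_gff3(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.name.replace(' ', '_').replace(';', ',')};Name={g.name}"
            fh.write(
                f"{g.contig}\tbactarget\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        name = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"))
        genes.append(GeneModel(f[0], int(f[3]), int(f[4]), f[6], name))
    return genes


# --------------------------------------------------------------------- difference reports

_RECORD_COLUMNS = [
    "contig", "position", "ref", "alt", "kind", "depth", "alt_fwd", "alt_rev",
    "alt_fraction", "assembly_coverage", "wildtype_shared", "low_coverage_region",
    "failed_verification", "annotation",
]


def records_to_frame(
    records: Sequence[DifferenceRecord], strains: Sequence[str] = ALL_STRAINS
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _RECORD_COLUMNS}
        row["alt"] = r.alt if r.alt else "-"
        for s in strains:
            row[s] = "X" if r.presence.get(s, False) else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS + list(strains))


def write_difference_report(
    path: str | Path, records: Sequence[DifferenceRecord],
    strains: Sequence[str] = ALL_STRAINS,
) -> None:
    records_to_frame(records, strains).to_csv(path, sep="\t", index=False)


def read_difference_report(path: str | Path) -> list[DifferenceRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    strains = [c for c in df.columns if c not in _RECORD_COLUMNS]
    records = []
    for _, row in df.iterrows():
        alt = "" if row["alt"] == "-" else row["alt"]
        cov = row["assembly_coverage"]
        records.append(
            DifferenceRecord(
                contig=row["contig"], position=int(row["position"]),
                ref=row["ref"], alt=alt, kind=row["kind"],
                presence={s: row[s] == "X" for s in strains},
                depth=int(row["depth"]), alt_fwd=int(row["alt_fwd"]),
                alt_rev=int(row["alt_rev"]), alt_fraction=float(row["alt_fraction"]),
                assembly_coverage=None if pd.isna(cov) else float(cov),
                wildtype_shared=bool(row["wildtype_shared"]),
                low_coverage_region=bool(row["low_coverage_region"]),
                failed_verification=bool(row["failed_verification"]),
                annotation="" if pd.isna(row["annotation"]) else str(row["annotation"]),
            )
        )
    return records


# --------------------------------------------------------------------- misc tables

def write_coverage_track(path: str | Path, coverage: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tcoverage\n")
        for contig in sorted(coverage):
            for i, c in enumerate(coverage[contig], start=1):
                fh.write(f"{contig}\t{i}\t{int(c)}\n")


def read_coverage_track(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        contig: grp.sort_values("position")["coverage"].to_numpy()
        for contig, grp in df.groupby("contig")
    }


def write_truth_manifest(path: str | Path, specs: Sequence[MutationSpec]) -> None:
    rows = [
        {
            "contig": s.contig, "position": s.position, "ref": s.ref,
            "alt": s.alt if s.alt else "-", "kind": s.kind,
            "strains": ",".join(s.strains),
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_manifest(path: str | Path) -> list[MutationSpec]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        MutationSpec(
            row["contig"], int(row["position"]), row["ref"],
            "" if row["alt"] == "-" else row["alt"],
            tuple(row["strains"].split(",")) if row["strains"] else (),
        )
        for _, row in df.iterrows()
    ]


def write_topology(path: str | Path, topo: TopologyModel) -> None:
    with open(path, "w") as fh:
        fh.write("helix\tstart\tend\tloop_side_after\n")
        for i, (s, e) in enumerate(topo.helices, start=1):
            fh.write(f"{i}\t{s}\t{e}\t{topo.loop_side(i)}\n")


def read_topology(path: str | Path, n_terminus_side: str = "cytoplasmic") -> TopologyModel:
    df = pd.read_csv(path, sep="\t")
    helices = [(int(r["start"]), int(r["end"])) for _, r in df.iterrows()]
    return TopologyModel(helices=helices, n_terminus_side=n_terminus_side)


# --------------------------------------------------------------------- plates

def write_plate_csv(
    path: str | Path, plates: Mapping[str, DilutionSeries]
) -> None:
    """One row per strain/replicate; columns are concentrations plus controls."""
    first = next(iter(plates.values()))
    conc = list(first.concentrations)
    with open(path, "w") as fh:
        fh.write("strain," + ",".join(f"{c:g}" for c in conc) + ",blank,control\n")
        for name, series in plates.items():
            if list(series.concentrations) != conc:
                raise ValueError("all plates in one file must share the dilution ladder")
            fh.write(
                f"{name},"
                + ",".join(f"{v:.5f}" for v in series.od)
                + f",{series.blank_od:.5f},{series.control_od:.5f}\n"
            )


def read_plate_csv(path: str | Path) -> dict[str, DilutionSeries]:
    df = pd.read_csv(path)
    conc = [float(c) for c in df.columns[1:-2]]
    out = {}
    for _, row in df.iterrows():
        out[str(row.iloc[0])] = DilutionSeries(
            concentrations=np.array(conc),
            od=row.iloc[1:-2].to_numpy(dtype=float),
            blank_od=float(row["blank"]),
            control_od=float(row["control"]),
        )
    return out


# --------------------------------------------------------------------- config

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(path: str | Path, data: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)


def config_hash(data: Mapping) -> str:
    return hashlib.sha256(json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:12]
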