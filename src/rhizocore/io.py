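"""File readers/writers for the pipeline's text formats.

All tabular I/O is UTF-8 with a mandatory header row; sample ids key the
rows. Networks go out as GraphML plus a 3-column edge-list TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community_table import OtuTable
from .correlation_network import KeystoneSet, ModulePartition
from .module_function import FunctionalProfile
from .process_rates import TimeSeries


# ---------- tabular ----------

def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_otu_table(path: str | Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns:  # row-oriented taxonomy not supported; column form
        taxonomy = df.pop("taxonomy").to_dict()
    return OtuTable.from_frame(df, taxonomy=taxonomy)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.index.name = "sample_id"
    metadata.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_functional_profile(fp: FunctionalProfile, path: str | Path) -> None:
    fp.data.index.name = "sample_id"
    fp.data.to_csv(path, sep="\t")


def read_functional_profile(path: str | Path) -> FunctionalProfile:
    return FunctionalProfile(pd.read_csv(path, sep="\t", index_col=0))


def write_timeseries(series: list[TimeSeries], path: str | Path) -> None:
    rows = [
        {"sample": ts.sample_id, "assay": ts.assay, "time_h": t, "value": v}
        for ts in series
        for t, v in zip(ts.times, ts.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timeseries(path: str | Path) -> list[TimeSeries]:
    df = pd.read_csv(path)
    out = []
    for (sample, assay), sub in df.groupby(["sample", "assay"], sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            TimeSeries(
                sample_id=str(sample),
                times=sub["time_h"].to_numpy(),
                values=sub["value"].to_numpy(),
                assay=str(assay),
            )
        )
    return out


# ---------- sequences ----------

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------- network ----------

def write_network(net: nx.Graph, graphml_path: str | Path, edges_path: str | Path) -> None:
    nx.write_graphml(net, str(graphml_path))
    rows = [
        {"source": u, "target": v, "rho": d.get("rho")}
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho"]).to_csv(
        edges_path, sep="\t", index=False
    )


def write_partition(part: ModulePartition, path: str | Path) -> None:
    payload = {
        "module_of_node": dict(sorted(part.module_of_node.items())),
        "main_modules": part.main_modules,
        "modularity": part.modularity,
    }
    write_json(payload, path)


def write_keystones(ks: KeystoneSet, path: str | Path) -> None:
    write_json({"nodes": ks.nodes, "scores": ks.scores}, path)


# ---------- generic ----------

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _json_default(o):
    try:
        return o.item()  # numpy scalars
    except AttributeError:
        raise TypeError(f"not JSON serializable: {type(o)}")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
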