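"""Delimited-text readers/writers and run configuration.

All data flows through plain delimited text (comma by default, tab
accepted): genes are rows everywhere, the first column holds gene ids, and
for time-course data the header row is the numeric, strictly increasing
time grid.  Posterior samples are persisted as a directory of tidy CSV
tables plus a small YAML metadata file, and can be read back into a
:class:`~mdifuse.sampler.PosteriorSamples`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import DatasetView
from .sampler import PosteriorSamples


# ---------------------------------------------------------------------------
# dataset files
# ---------------------------------------------------------------------------

def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if first.count("\t") > first.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing/ragged value at gene {bad!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return df


def read_dataset(path, data_type: str, name: str | None = None,
                 sep: str | None = None) -> DatasetView:
    """Read one delimited dataset file into a validated view.

    ``data_type`` is one of ``timecourse`` / ``categorical`` /
    ``bag_of_words``; for time courses the header must parse as a strictly
    increasing numeric grid.
    """
    df = _read_table(path, sep=sep)
    name = name or Path(path).stem
    time = None
    if data_type == "timecourse":
        try:
            time = df.columns.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: time-course header must be numeric, got "
                f"{list(df.columns)[:5]}") from exc
        if time.size > 1 and not np.all(np.diff(time) > 0):
            raise ValueError(
                f"{path}: time header is not strictly increasing: {time.tolist()}")
        matrix = df.to_numpy(dtype=float)
    else:
        try:
            matrix = df.to_numpy(dtype=np.int64)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-integer cell in {data_type} data") from exc
    view = DatasetView(name=name, data_type=data_type, matrix=matrix,
                       gene_ids=list(df.index.astype(str)), time=time)
    return view


def write_dataset(view: DatasetView, path, sep: str = ",") -> None:
    if view.data_type == "timecourse":
        cols = [f"{t:g}" for t in view.time]
    elif view.data_type == "bag_of_words":
        cols = list(view.vocabulary)
    else:
        cols = [f"f{j}" for j in range(view.n_features)]
    df = pd.DataFrame(view.matrix, index=pd.Index(view.gene_ids, name="gene_id"),
                      columns=cols)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DatasetEntry:
    path: str
    data_type: str
    name: str | None = None


@dataclasses.dataclass
class RunConfig:
    """Serializable description of one fitting run."""

    datasets: list
    n_components: int | None = None
    n_iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 5
    seed: int = 0
    prior_mass: tuple = (2.0, 4.0)
    prior_phi: tuple = (1.0, 0.2)
    threshold: float = 0.5
    update_phi: bool = True
    output_dir: str = "mdifuse_out"

    def __post_init__(self):
        self.datasets = [d if isinstance(d, DatasetEntry) else DatasetEntry(**d)
                         for d in self.datasets]
        if not self.datasets:
            raise ValueError("config lists no datasets")
        self.prior_mass = tuple(self.prior_mass)
        self.prior_phi = tuple(self.prior_phi)

    def validate_paths(self) -> None:
        for d in self.datasets:
            if not Path(d.path).exists():
                raise FileNotFoundError(f"dataset file not found: {d.path}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["prior_mass"] = list(self.prior_mass)
        out["prior_phi"] = list(self.prior_phi)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_views(config: RunConfig):
    config.validate_paths()
    return [read_dataset(d.path, d.data_type, name=d.name) for d in config.datasets]


# ---------------------------------------------------------------------------
# posterior sample persistence
# ---------------------------------------------------------------------------

def save_samples(samples: PosteriorSamples, outdir) -> None:
    """Write snapshots and traces as tidy CSVs plus a YAML metadata file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    S, n, K = samples.allocations.shape

    it = np.repeat(samples.iterations, n * K)
    ds = np.tile(np.repeat(np.arange(K), 1), (S * n,))
    gene = np.tile(np.repeat(np.arange(n), K), S)
    pd.DataFrame({
        "iteration": it,
        "gene_id": [samples.gene_ids[g] for g in gene],
        "dataset": [samples.dataset_names[d] for d in ds],
        "label": samples.allocations.reshape(-1),
    }).to_csv(outdir / "allocations.csv", index=False)

    from .core import edge_index
    rows = []
    for e, (k, l) in enumerate(edge_index(K)):
        for s in range(S):
            rows.append((int(samples.iterations[s]), e,
                         samples.dataset_names[k], samples.dataset_names[l],
                         samples.phi[s, e]))
    pd.DataFrame(rows, columns=["iteration", "edge", "dataset_k", "dataset_l",
                                "value"]).to_csv(outdir / "phi_trace.csv", index=False)

    rows = []
    for k in range(K):
        for s in range(S):
            rows.append((int(samples.iterations[s]), samples.dataset_names[k],
                         samples.mass[s, k]))
    pd.DataFrame(rows, columns=["iteration", "dataset", "value"]).to_csv(
        outdir / "alpha_trace.csv", index=False)

    pd.DataFrame({"iteration": samples.iterations, "value": samples.v}).to_csv(
        outdir / "v_trace.csv", index=False)

    meta = {
        "gene_ids": list(samples.gene_ids),
        "dataset_names": list(samples.dataset_names),
        "n_components": int(samples.n_components),
        "iterations": [int(x) for x in samples.iterations],
        "config": samples.config,
    }
    with open(outdir / "samples_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_samples(outdir) -> PosteriorSamples:
    outdir = Path(outdir)
    with open(outdir / "samples_meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    gene_ids = [str(g) for g in meta["gene_ids"]]
    names = [str(d) for d in meta["dataset_names"]]
    iters = np.asarray(meta["iterations"], dtype=np.int64)
    S, n, K = len(iters), len(gene_ids), len(names)

    al = pd.read_csv(outdir / "allocations.csv")
    gpos = {g: i for i, g in enumerate(gene_ids)}
    dpos = {d: i for i, d in enumerate(names)}
    ipos = {int(v): i for i, v in enumerate(iters)}
    alloc = np.zeros((S, n, K), dtype=np.int16)
    alloc[al["iteration"].map(ipos), al["gene_id"].map(gpos),
          al["dataset"].map(dpos)] = al["label"].to_numpy()

    pt = pd.read_csv(outdir / "phi_trace.csv")
    E = K * (K - 1) // 2
    phi = np.zeros((S, E))
    if E:
        phi[pt["iteration"].map(ipos), pt["edge"]] = pt["value"].to_numpy()

    at = pd.read_csv(outdir / "alpha_trace.csv")
    mass = np.zeros((S, K))
    mass[at["iteration"].map(ipos), at["dataset"].map(dpos)] = at["value"].to_numpy()

    vt = pd.read_csv(outdir / "v_trace.csv")
    v = np.zeros(S)
    v[vt["iteration"].map(ipos)] = vt["value"].to_numpy()

    return PosteriorSamples(allocations=alloc, phi=phi, mass=mass, v=v,
                            iterations=iters, gene_ids=gene_ids,
                            dataset_names=names,
                            n_components=int(meta["n_components"]),
                            config=meta.get("config") or {})
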