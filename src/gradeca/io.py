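"""Matrix readers/writers, result serialisation and the pipeline driver."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grade import DataMatrix, grade_density, to_probability_matrix

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "RunConfig", "run_pipeline"]

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _SEPS:
            raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
        return _SEPS[fmt]
    return _SEPS.get(path.suffix.lstrip(".").lower(), "\t")


def read_matrix(path, fmt: str | None = None, chunksize: int = 2048) -> DataMatrix:
    """Read a labelled numeric matrix from TSV/CSV.

    First row = column ids, first column = row ids, strict C-locale decimal
    points.  Duplicate ids, NA cells and malformed numerics are rejected with
    coordinates.  Files are read in row chunks so very wide matrices never
    require more than the final array plus one chunk in memory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path, fmt)
    chunks = []
    row_ids: list[str] = []
    col_ids = None
    for chunk in pd.read_csv(
        path, sep=sep, index_col=0, chunksize=chunksize,
        na_filter=True, dtype=str,
    ):
        if col_ids is None:
            col_ids = [str(c) for c in chunk.columns]
            if len(set(col_ids)) != len(col_ids):
                dup = sorted({c for c in col_ids if col_ids.count(c) > 1})
                raise ValueError(f"duplicate column ids: {dup}")
        if chunk.isna().any().any():
            r, c = next(
                (r, c) for r in chunk.index for c in chunk.columns
                if pd.isna(chunk.at[r, c])
            )
            raise ValueError(f"missing value at row {r!r}, column {c!r}")
        try:
            arr = chunk.to_numpy(dtype=str).astype(float)
        except ValueError:
            for r in chunk.index:
                for c in chunk.columns:
                    try:
                        float(chunk.at[r, c])
                    except ValueError:
                        raise ValueError(
                            f"malformed numeric {chunk.at[r, c]!r} at "
                            f"row {r!r}, column {c!r}"
                        ) from None
            raise
        chunks.append(arr)
        row_ids.extend(str(r) for r in chunk.index)
    if not chunks:
        raise ValueError(f"{path}: empty matrix")
    if len(set(row_ids)) != len(row_ids):
        dup = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise ValueError(f"duplicate row ids: {dup}")
    values = np.vstack(chunks)
    return DataMatrix(values, row_ids, col_ids)


def write_matrix(m: DataMatrix, path, fmt: str | None = None,
                 float_format: str = "%.10g") -> None:
    path = Path(path)
    sep = _sep_for(path, fmt)
    m.to_dataframe().to_csv(path, sep=sep, float_format=float_format)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclasses.dataclass
class RunConfig:
    """Validated parameters of a full GCA -> GCCA -> selection run; written
    alongside every result bundle for provenance."""

    objective: str = "rho"
    restarts: int = 20
    seed: int = 0
    tol: float = 1e-12
    max_iter: int = 100
    row_clusters: int = 6
    col_clusters: int = 6
    threshold: float = 1.3
    group_a: tuple[int, ...] = (1, 2)
    group_b: tuple[int, ...] = (5, 6)
    colormap: str = "Greys"
    log_level: str = "INFO"
    max_candidates: int = 4096

    def __post_init__(self):
        if self.objective not in ("rho", "tau"):
            raise ValueError(f"objective must be rho|tau, got {self.objective!r}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.row_clusters < 1 or self.col_clusters < 1:
            raise ValueError("cluster counts must be >= 1")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        self.group_a = tuple(int(x) for x in self.group_a)
        self.group_b = tuple(int(x) for x in self.group_b)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, input_path, outdir, render: bool = True) -> dict:
    """Order -> cluster -> aggregate -> differential selection, writing
    ordering.json, clusters.json, profiles.tsv, genes.tsv, map.png and a run
    log into ``outdir``.  Returns the paths and headline numbers."""
    from .casestats import GroupContrast, differential_selection
    from .seriation import GCA

    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        m = read_matrix(input_path)
        logger.info("read %d x %d matrix from %s", *m.shape, input_path)

        stage = "order"
        res = GCA(m, objective=config.objective).fit(
            restarts=config.restarts,
            max_iter=config.max_iter,
            seed=config.seed,
            tol=config.tol,
        )
        write_json(res.ordering.to_dict(), outdir / "ordering.json")
        logger.info("GCA achieved %s = %.6f", config.objective, res.achieved)

        stage = "cluster"
        Kr = min(config.row_clusters, m.shape[0])
        Kc = min(config.col_clusters, m.shape[1])
        cres = res.segment(Kr=Kr, Kc=Kc, max_candidates=config.max_candidates)
        clusters = cres.clusters.to_dict()
        clusters["row_members"] = {
            str(c): [i for i, l in cres.row_labels().items() if l == c]
            for c in range(1, Kr + 1)
        }
        clusters["col_members"] = {
            str(c): [j for j, l in cres.col_labels().items() if l == c]
            for c in range(1, Kc + 1)
        }
        write_json(clusters, outdir / "clusters.json")

        stage = "aggregate"
        profile = cres.median_profile(axis="rows")
        profile.to_dataframe().to_csv(outdir / "profiles.tsv", sep="\t")

        stage = "select"
        ga = tuple(l for l in config.group_a if l <= Kr)
        gb = tuple(l for l in config.group_b if l <= Kr)
        if not ga or not gb or set(ga) & set(gb):
            logger.warning(
                "contrast groups %s vs %s do not fit %d row clusters; "
                "falling back to extremes (1) vs (%d)",
                config.group_a, config.group_b, Kr, Kr,
            )
            ga, gb = (1,), (Kr,)
        diff = differential_selection(
            profile, GroupContrast(ga, gb, config.threshold)
        )
        diff.to_dataframe().to_csv(outdir / "genes.tsv", sep="\t", index=False)

        map_path = None
        if render:
            stage = "render"
            from .plotting import render_overrepresentation

            map_path = outdir / "map.png"
            render_overrepresentation(
                grade_density(res.ordered_probability),
                model=cres.clusters,
                path=map_path,
                colormap=config.colormap,
            )

        stage = "log"
        record = {
            "config": config.to_dict(),
            "input": str(input_path),
            "n": m.shape[0],
            "k": m.shape[1],
            "achieved": res.achieved,
            "criterion": cres.criterion,
            "n_selected_genes": len(diff.records),
            "outputs": {
                "ordering": str(outdir / "ordering.json"),
                "clusters": str(outdir / "clusters.json"),
                "profiles": str(outdir / "profiles.tsv"),
                "genes": str(outdir / "genes.tsv"),
                "map": str(map_path) if map_path else None,
            },
        }
        write_json(record, outdir / "run.json")
        return record
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
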