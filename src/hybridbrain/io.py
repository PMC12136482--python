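"""File formats, synthetic connectome generation and run manifests.

Connectomes are read from TVB-style layouts — a directory or zip archive
with whitespace-delimited ``weights.txt`` and ``tract_lengths.txt``
(optionally ``centres.txt`` providing region names) — or from a pair of
CSV matrices. Activity traces and spike rasters use plain-text formats.

The synthetic connectome generator emulates the gross statistics of an
atlas-derived whole-brain structural connectivity: ~100 regions in two
mirror-symmetric hemispheres, log-normal positive weights, and uniform
tract lengths on a biological range.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .massmodel import Connectome
from .network import SpikeRaster

__all__ = [
    "SyntheticConnectomeSpec",
    "synthetic_connectome",
    "read_connectome",
    "write_connectome",
    "write_raster",
    "read_raster",
    "write_manifest",
    "read_manifest",
]


# --------------------------------------------------------------------------
# synthetic connectome
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConnectomeSpec:
    """Parameters of the surrogate whole-brain connectome.

    With ``hemisphere_symmetry`` the two halves mirror each other: the
    intra-hemispheric blocks are identical and the inter-hemispheric block
    is symmetric under swapping hemispheres. Weights are log-normal
    (``weight_mu``/``weight_sigma`` on the log scale), tract lengths are
    uniform on ``length_range`` (mm) and quantized to ``length_step`` so
    that conduction delays land on the integration grid.
    """

    n_regions: int = 98
    hemisphere_symmetry: bool = True
    weight_mu: float = -2.0
    weight_sigma: float = 1.0
    length_range: tuple[float, float] = (3.0, 60.0)
    length_step: float = 0.3
    density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.hemisphere_symmetry and self.n_regions % 2:
            raise ValueError("hemisphere symmetry needs an even region count")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ValueError("length_range must be positive and ordered")


def synthetic_connectome(spec: SyntheticConnectomeSpec | None = None) -> Connectome:
    """Deterministic surrogate connectome for the given spec."""
    spec = spec or SyntheticConnectomeSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions

    def block(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
        mask = rng.random((rows, cols)) < spec.density
        w = np.exp(rng.normal(spec.weight_mu, spec.weight_sigma, (rows, cols)))
        lo, hi = spec.length_range
        steps = int(round((hi - lo) / spec.length_step))
        L = lo + spec.length_step * rng.integers(0, steps + 1, (rows, cols))
        w = np.where(mask, w, 0.0)
        L = np.where(mask, L, 0.0)
        return w, L

    if spec.hemisphere_symmetry:
        h = n // 2
        w_intra, L_intra = block(h, h)
        w_inter, L_inter = block(h, h)
        weights = np.block([[w_intra, w_inter], [w_inter, w_intra]])
        lengths = np.block([[L_intra, L_inter], [L_inter, L_intra]])
        labels = [f"l R{i:02d}" for i in range(h)] + [f"r R{i:02d}" for i in range(h)]
    else:
        weights, lengths = block(n, n)
        labels = [f"R{i:02d}" for i in range(n)]
    np.fill_diagonal(weights, 0.0)
    np.fill_diagonal(lengths, 0.0)
    return Connectome(labels=labels, weights=weights, tract_lengths=lengths)


# --------------------------------------------------------------------------
# connectome I/O
# --------------------------------------------------------------------------

def _parse_centres(text: str) -> list[str]:
    labels = []
    for line in text.strip().splitlines():
        parts = line.split()
        if parts:
            labels.append(parts[0])
    return labels


def read_connectome(path: str | Path, speed: float = 3.0) -> Connectome:
    """Read a connectome from a TVB-style zip/directory or a CSV pair.

    Accepted layouts:

    - directory or ``.zip`` containing ``weights.txt`` and
      ``tract_lengths.txt`` (whitespace-delimited matrices) and optionally
      ``centres.txt`` whose first column holds region names;
    - a directory containing ``weights.csv`` and ``tract_lengths.csv``.
    """
    path = Path(path)

    def load_pair(read):
        w = np.loadtxt(read("weights"))
        L = np.loadtxt(read("tract_lengths"))
        return w, L

    labels = None
    if path.suffix == ".zip":
        with zipfile.ZipFile(path) as zf:
            names = {Path(n).stem: n for n in zf.namelist()}
            if "weights" not in names or "tract_lengths" not in names:
                raise FileNotFoundError(
                    f"{path} lacks weights/tract_lengths entries")
            import io as _io

            def read(stem):
                return _io.BytesIO(zf.read(names[stem]))

            w, L = load_pair(read)
            if "centres" in names:
                labels = _parse_centres(zf.read(names["centres"]).decode())
    elif path.is_dir():
        txt_w = path / "weights.txt"
        csv_w = path / "weights.csv"
        if txt_w.exists():
            w = np.loadtxt(txt_w)
            L = np.loadtxt(path / "tract_lengths.txt")
        elif csv_w.exists():
            w = np.loadtxt(csv_w, delimiter=",")
            L = np.loadtxt(path / "tract_lengths.csv", delimiter=",")
        else:
            raise FileNotFoundError(f"no weights.txt or weights.csv in {path}")
        centres = path / "centres.txt"
        if centres.exists():
            labels = _parse_centres(centres.read_text())
    else:
        raise FileNotFoundError(f"{path} is neither a directory nor a zip")

    w = np.atleast_2d(np.asarray(w, dtype=float))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"weights matrix is not square: {w.shape}")
    if w.shape != L.shape:
        raise ValueError(
            f"weights {w.shape} and tract_lengths {L.shape} differ in shape")
    if labels is None:
        labels = [f"R{i:02d}" for i in range(w.shape[0])]
    if len(labels) != w.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for {w.shape[0]} regions")
    return Connectome(labels=labels, weights=w, tract_lengths=L, speed=speed)


def write_connectome(conn: Connectome, path: str | Path, fmt: str = "dir") -> Path:
    """Write weights/tract_lengths/centres as a TVB-style directory or zip."""
    path = Path(path)

    def render(arr):
        return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in arr) + "\n"

    centres = "".join(f"{lab.replace(' ', '_')} 0.0 0.0 0.0\n"
                      for lab in conn.labels)
    if fmt == "zip" or path.suffix == ".zip":
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.txt", render(conn.weights))
            zf.writestr("tract_lengths.txt", render(conn.tract_lengths))
            zf.writestr("centres.txt", centres)
    else:
        path.mkdir(parents=True, exist_ok=True)
        (path / "weights.txt").write_text(render(conn.weights))
        (path / "tract_lengths.txt").write_text(render(conn.tract_lengths))
        (path / "centres.txt").write_text(centres)
    return path


# --------------------------------------------------------------------------
# rasters and traces
# --------------------------------------------------------------------------

def write_raster(raster: SpikeRaster, path: str | Path) -> Path:
    """Two-column text: gid, time (ms)."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("# gid t_ms\n")
        for g, t in zip(raster.gids, raster.times):
            f.write(f"{g} {t:.17g}\n")
    return path


def read_raster(path: str | Path) -> SpikeRaster:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return SpikeRaster.empty()
    return SpikeRaster(times=data[:, 1], gids=data[:, 0].astype(np.int64))


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path: str | Path, config: dict, seeds: dict,
                   extra: dict | None = None) -> Path:
    """JSON manifest from which a stochastic run is exactly re-derivable.

    ``seeds`` must name every RNG stream used by the run; a missing or
    None seed is an error (the output would not be reproducible).
    """
    if not seeds:
        raise ValueError("manifest requires at least one named seed")
    for name, value in seeds.items():
        if value is None:
            raise ValueError(f"seed {name!r} is None; run is not reproducible")
    import hybridbrain

    doc = {
        "package": "hybridbrain",
        "version": getattr(hybridbrain, "__version__", "unknown"),
        "config": _jsonable(config),
        "seeds": _jsonable(seeds),
    }
    if extra:
        doc["extra"] = _jsonable(extra)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
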