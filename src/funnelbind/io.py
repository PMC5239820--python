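"""Plain-text readers and writers plus the run configuration.

Hills and collective-variable files use the PLUMED-1.x style: whitespace
separated columns, ``#`` comment lines, and a ``#! FIELDS`` header naming
the columns.  Numbers are written with the shortest decimal representation
that round-trips the IEEE double, so writer -> reader -> writer is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bias import CoordinationRestraint, FunnelGeometry, HillsRecord, WTParams
from .binding import BindingConfig, RestraintSeries
from .engine import Trajectory
from .fes import GridSpec, Pmf

__all__ = [
    "read_hills", "write_hills", "read_colvar", "write_colvar",
    "colvar_to_trajectory", "colvar_to_restraint_series",
    "write_pmf", "read_pmf", "RunConfig",
]

_HILLS_FIELDS = ["time", "cv1", "cv2", "sigma_cv1", "sigma_cv2", "height",
                 "biasf"]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_hills(path, hills: HillsRecord, comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#! FIELDS " + " ".join(_HILLS_FIELDS) + "\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for i in range(len(hills)):
            row = [hills.times[i], hills.centers[i, 0], hills.centers[i, 1],
                   hills.widths[i, 0], hills.widths[i, 1], hills.heights[i],
                   hills.gamma]
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_hills(path) -> HillsRecord:
    """Parse a hills file; comment lines are skipped, malformed lines are
    reported with their line number."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != len(_HILLS_FIELDS):
                raise ValueError(
                    f"{path}:{ln}: expected {len(_HILLS_FIELDS)} columns, "
                    f"got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no hills")
    arr = np.array(rows)
    gammas = np.unique(arr[:, 6])
    if gammas.size != 1:
        raise ValueError(f"{path}: inconsistent bias factors {gammas}")
    try:
        return HillsRecord(times=arr[:, 0], centers=arr[:, 1:3],
                           widths=arr[:, 3:5], heights=arr[:, 5],
                           gamma=float(gammas[0]))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_colvar(path, traj: Trajectory, header: dict | None = None) -> None:
    """COLVAR-style output: time, cv1, then whichever of cv2 / S /
    restraint_energy the trajectory carries."""
    fields = ["time", "cv1"]
    cols = [traj.times, traj.cv1]
    if traj.cv2 is not None:
        fields.append("cv2")
        cols.append(traj.cv2)
    if traj.S is not None:
        fields.append("coord_S")
        cols.append(traj.S)
    if traj.V_S is not None:
        fields.append("restraint_energy")
        cols.append(traj.V_S)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        meta = dict(header or {})
        if traj.seed is not None:
            meta.setdefault("seed", traj.seed)
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        for row in zip(*cols):
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def read_colvar(path) -> dict[str, np.ndarray]:
    """Parse a COLVAR-style file into ``{column name: array}``.

    Column names come from the ``#! FIELDS`` header; without one the
    columns are named col0, col1, ...
    """
    path = Path(path)
    names: list[str] | None = None
    rows = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if s.startswith("#!") and "FIELDS" in s:
                names = s.split()[2:]
                continue
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if names is not None and len(parts) != len(names):
                raise ValueError(
                    f"{path}:{ln}: expected {len(names)} columns, "
                    f"got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    if names is None:
        names = [f"col{i}" for i in range(arr.shape[1])]
    return {n: arr[:, i] for i, n in enumerate(names)}


def colvar_to_trajectory(cols: dict[str, np.ndarray],
                         mapping: dict[str, str] | None = None) -> Trajectory:
    """Build a Trajectory from parsed colvar columns.

    ``mapping`` renames file columns onto the canonical names ``time``,
    ``cv1``, ``cv2``, ``coord_S``, ``restraint_energy``.
    """
    if mapping:
        cols = {mapping.get(k, k): v for k, v in cols.items()}
    if "time" not in cols or "cv1" not in cols:
        raise ValueError("colvar data must provide 'time' and 'cv1' columns")
    return Trajectory(times=cols["time"], cv1=cols["cv1"],
                      cv2=cols.get("cv2"), S=cols.get("coord_S"),
                      V_S=cols.get("restraint_energy"))


def colvar_to_restraint_series(cols: dict[str, np.ndarray],
                               mapping: dict[str, str] | None = None
                               ) -> RestraintSeries:
    """Extract the V(S) series for FEP; the time column must be uniform and
    the restraint-energy column present."""
    if mapping:
        cols = {mapping.get(k, k): v for k, v in cols.items()}
    if "restraint_energy" not in cols:
        raise ValueError(
            "no restraint_energy column: cannot build a FEP input series")
    t = np.asarray(cols["time"], dtype=float)
    if t.size < 2:
        raise ValueError("restraint series needs at least two frames")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError("non-uniform time column in restraint series")
    return RestraintSeries(times=t, V_S=cols["restraint_energy"],
                           dt_out=float(dt[0]))


def write_pmf(path, pmf: Pmf, header: dict | None = None) -> None:
    """Two-column (z, w) text table with ``#`` metadata, gnuplot-friendly."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#! FIELDS z pmf\n")
        meta = {"T": pmf.T, "referenced": pmf.referenced,
                "ref_range": pmf.ref_range, **(header or {})}
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        for z, w in zip(pmf.z, pmf.w):
            fh.write(f"{_fmt(z)} {_fmt(w)}\n")


def read_pmf(path) -> Pmf:
    cols = read_colvar(path)
    key = "pmf" if "pmf" in cols else "col1"
    z = cols["z"] if "z" in cols else cols["col0"]
    w = cols[key]
    referenced = False
    T = 298.0
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("# referenced:"):
                referenced = line.split(":", 1)[1].strip() == "True"
            elif line.startswith("# T:"):
                T = float(line.split(":", 1)[1])
    return Pmf(z=z, w=w, sampled=np.ones(z.size, dtype=bool), T=T,
               referenced=referenced)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Aggregated configuration of a full toy-protocol run.

    Defaults equal the published all-atom protocol wherever one exists
    (funnel geometry, deposition parameters, water-restraint constants,
    standard-state conventions); engine and analysis settings are the toy
    defaults.  Round-trips through YAML bit-identically.
    """

    funnel: FunnelGeometry = field(default_factory=FunnelGeometry)
    restraint: CoordinationRestraint = field(
        default_factory=CoordinationRestraint)
    wt: WTParams = field(default_factory=WTParams)
    binding: BindingConfig = field(default_factory=BindingConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    preset: str = "double_well"
    nsteps: int = 500_000
    dt: float = 0.01
    seed: int = 0
    window: float = 2000.0       # averaging window W for final_estimate, ps
    eval_stride: float = 100.0   # dG_meta(t) evaluation stride, ps

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["binding"]["ref_range"] = list(d["binding"]["ref_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        b = dict(d.pop("binding"))
        b["ref_range"] = tuple(b["ref_range"])
        return cls(funnel=FunnelGeometry(**d.pop("funnel")),
                   restraint=CoordinationRestraint(**d.pop("restraint")),
                   wt=WTParams(**d.pop("wt")),
                   binding=BindingConfig(**b),
                   grid=GridSpec(**d.pop("grid")), **d)

    def save(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        import hashlib
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
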