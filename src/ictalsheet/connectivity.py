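"""Lateral coupling of the cortical sheet and in-silico resections.

Three sparse column-to-column operators are built:

* ``W_EE_local`` -- local feed-forward excitation (E output to E input),
* ``W_EI_local`` -- local feed-forward inhibition (E output to the target's
  I population; the weight itself is positive, suppression happens through
  the target's inhibitory population),
* ``W_EE_remote`` -- patchy long-range excitation: each source column
  projects to a small number of distant clusters of columns.

Local edges are drawn per source column with probability
``p0_local * exp(-d / decay)`` up to a hard cutoff ``local_radius``; remote
cluster centres are sampled uniformly (by area) in a distance annulus.
Rows (targets) are rescaled so the realized in-weight sum equals the
configured lateral weight, making total lateral input degree-independent:
a homogeneous sheet then behaves exactly like a single effective unit with
couplings ``C_EE + w_EE_local + w_EE_remote`` and ``C_EI + w_EI_local``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from .model_core import SheetGeometry

__all__ = [
    "ConnectivityConfig",
    "ConnectivityMatrices",
    "ResectionMask",
    "build_connectivity",
    "apply_resection",
    "place_microdomains",
    "save_connectivity",
    "load_connectivity",
]


@dataclass(frozen=True)
class ConnectivityConfig:
    """Parameters of the lateral connectivity generator (distances in
    minicolumns)."""

    local_radius: float = 4.0
    p0_local: float = 0.3
    decay: float = 2.0
    w_EE_local: float = 11.0
    w_EI_local: float = 12.0
    w_EE_remote: float = 2.0
    n_remote_clusters: float = 4.0
    remote_distance_range: tuple = (20.0, 60.0)
    cluster_radius: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0_local <= 1.0):
            raise ValueError("p0_local must be a probability")
        lo, hi = self.remote_distance_range
        if self.local_radius > 0 and lo <= self.local_radius:
            raise ValueError("remote distances must exceed local_radius")
        if lo > hi or lo <= 0:
            raise ValueError("invalid remote_distance_range")
        if self.local_radius < 0 or self.cluster_radius < 0:
            raise ValueError("radii must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["remote_distance_range"] = list(self.remote_distance_range)
        return d


@dataclass
class ConnectivityMatrices:
    """Sparse lateral operators; entry (i, j) weights source j onto target i."""

    W_EE_local: sparse.csr_matrix
    W_EI_local: sparse.csr_matrix
    W_EE_remote: sparse.csr_matrix
    geometry: SheetGeometry
    provenance: dict = field(default_factory=dict)

    def matrices(self):
        return (self.W_EE_local, self.W_EI_local, self.W_EE_remote)


@dataclass
class ResectionMask:
    """Set of removed minicolumns.  The default surgical shape is a strip of
    30 contiguous lattice columns spanning all rows (20% of a 150x150 sheet).
    """

    indices: np.ndarray
    shape: str = "custom"

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=np.int64))

    @classmethod
    def strip(cls, geometry: SheetGeometry, col_start: int, width: int = 30):
        """All rows x ``width`` lattice columns starting at ``col_start``."""
        if col_start < 0 or col_start + width > geometry.n_cols:
            raise ValueError("strip exceeds lattice")
        cols = np.arange(col_start, col_start + width)
        idx = (np.arange(geometry.n_rows)[:, None] * geometry.n_cols
               + cols[None, :]).ravel()
        return cls(idx, shape=f"strip[{geometry.n_rows}x{width}]@{col_start}")

    def bool_mask(self, geometry: SheetGeometry) -> np.ndarray:
        m = np.zeros(geometry.n_columns, dtype=bool)
        m[self.indices] = True
        return m


def _local_offsets(radius: float, p0: float, decay: float):
    """(dr, dc, prob) for all lattice offsets within the cutoff, no self."""
    r = int(np.floor(radius))
    dr, dc = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1),
                         indexing="ij")
    dr, dc = dr.ravel(), dc.ravel()
    d = np.hypot(dr, dc)
    keep = (d <= radius) & (d > 0)
    dr, dc, d = dr[keep], dc[keep], d[keep]
    return dr, dc, p0 * np.exp(-d / decay)


def _draw_local(geom: SheetGeometry, rng, dr, dc, prob):
    """Bernoulli edge draws for one local kernel; returns (targets, sources)."""
    rows = np.arange(geom.n_rows)
    cols = np.arange(geom.n_cols)
    src_r, src_c = np.meshgrid(rows, cols, indexing="ij")
    src_r, src_c = src_r.ravel(), src_c.ravel()
    tg, sc = [], []
    for k in range(len(dr)):
        hit = rng.random(geom.n_columns) < prob[k]
        tr = src_r + dr[k]
        tc = src_c + dc[k]
        ok = hit & (tr >= 0) & (tr < geom.n_rows) & (tc >= 0) & (tc < geom.n_cols)
        if ok.any():
            tg.append(tr[ok] * geom.n_cols + tc[ok])
            sc.append((src_r[ok] * geom.n_cols + src_c[ok]))
    if not tg:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(tg), np.concatenate(sc)


def _ensure_local_input(mat: sparse.csr_matrix,
                        geom: SheetGeometry) -> sparse.csr_matrix:
    """Give columns that drew no local in-edges their 4-neighbourhood.

    With a sparse kernel a few columns per sheet would otherwise receive no
    local drive at all and could never be recruited by their surround.
    """
    empty = np.flatnonzero(np.diff(mat.indptr) == 0)
    if len(empty) == 0:
        return mat
    er, ec = geom.rc(empty)
    tg, sc = [], []
    for drr, dcc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rr, cc = er + drr, ec + dcc
        ok = (rr >= 0) & (rr < geom.n_rows) & (cc >= 0) & (cc < geom.n_cols)
        tg.append(empty[ok])
        sc.append(rr[ok] * geom.n_cols + cc[ok])
    fill = sparse.csr_matrix(
        (np.ones(sum(len(t) for t in tg)),
         (np.concatenate(tg), np.concatenate(sc))), shape=mat.shape)
    return (mat + fill).tocsr()


def _row_normalize(mat: sparse.csr_matrix, total: float) -> sparse.csr_matrix:
    """Scale every non-empty row so its entries sum to ``total``."""
    rowsum = np.asarray(mat.sum(axis=1)).ravel()
    scale = np.zeros_like(rowsum)
    nz = rowsum > 0
    scale[nz] = total / rowsum[nz]
    return sparse.diags(scale).dot(mat).tocsr()


def build_connectivity(geometry: SheetGeometry,
                       config: ConnectivityConfig = ConnectivityConfig()
                       ) -> ConnectivityMatrices:
    """Generate the three lateral operators; bit-reproducible given the seed."""
    rng = np.random.default_rng(np.random.Philox(key=config.seed))
    n = geometry.n_columns
    shape = (n, n)

    def to_csr(tg, sc):
        off = tg != sc  # no self-edges; within-column coupling is scalar
        m = sparse.csr_matrix(
            (np.ones(off.sum()), (tg[off], sc[off])), shape=shape)
        m.data[:] = np.minimum(m.data, 1.0)  # collapse duplicate draws
        return m

    if config.local_radius > 0 and config.p0_local > 0:
        dr, dc, prob = _local_offsets(config.local_radius, config.p0_local,
                                      config.decay)
        ee = to_csr(*_draw_local(geometry, rng, dr, dc, prob))
        ei = to_csr(*_draw_local(geometry, rng, dr, dc, prob))
        ee = _ensure_local_input(ee, geometry)
        ei = _ensure_local_input(ei, geometry)
    else:
        ee = sparse.csr_matrix(shape)
        ei = sparse.csr_matrix(shape)

    truncated_clusters = 0
    if config.n_remote_clusters > 0:
        lo, hi = config.remote_distance_range
        n_cl = int(round(config.n_remote_clusters))
        src_r, src_c = geometry.rc(np.arange(n))
        tg_all, sc_all = [], []
        # disc offsets of one cluster
        cr = int(np.floor(config.cluster_radius))
        odr, odc = np.meshgrid(np.arange(-cr, cr + 1), np.arange(-cr, cr + 1),
                               indexing="ij")
        odr, odc = odr.ravel(), odc.ravel()
        disc = np.hypot(odr, odc) <= config.cluster_radius
        odr, odc = odr[disc], odc[disc]
        for _ in range(n_cl):
            ang = rng.uniform(0, 2 * np.pi, n)
            rad = np.sqrt(rng.uniform(lo ** 2, hi ** 2, n))
            ctr_r = np.rint(src_r + rad * np.sin(ang)).astype(np.int64)
            ctr_c = np.rint(src_c + rad * np.cos(ang)).astype(np.int64)
            tr = ctr_r[:, None] + odr[None, :]
            tc = ctr_c[:, None] + odc[None, :]
            ok = (tr >= 0) & (tr < geometry.n_rows) & \
                 (tc >= 0) & (tc < geometry.n_cols)
            truncated_clusters += int(np.sum(~ok.any(axis=1)))
            src_rep = np.broadcast_to(np.arange(n)[:, None], tr.shape)
            tg_all.append((tr[ok] * geometry.n_cols + tc[ok]))
            sc_all.append(src_rep[ok])
        er = to_csr(np.concatenate(tg_all), np.concatenate(sc_all))
    else:
        er = sparse.csr_matrix(shape)

    mats = ConnectivityMatrices(
        W_EE_local=_row_normalize(ee, config.w_EE_local),
        W_EI_local=_row_normalize(ei, config.w_EI_local),
        W_EE_remote=_row_normalize(er, config.w_EE_remote),
        geometry=geometry,
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "fully_truncated_remote_clusters": truncated_clusters,
            "rows_without_remote_input":
                int(np.sum(np.asarray(er.sum(axis=1)).ravel() == 0)),
        },
    )
    return mats


def apply_resection(conn: ConnectivityMatrices,
                    mask: ResectionMask) -> ConnectivityMatrices:
    """Remove every edge with source or target in the mask.

    Returns a new operator set; the input is left unmodified.  All surviving
    entries are bit-identical to the originals.
    """
    n = conn.geometry.n_columns
    if len(mask.indices) and (mask.indices.min() < 0 or mask.indices.max() >= n):
        raise ValueError("resection mask outside the lattice")
    keep = np.ones(n)
    keep[mask.indices] = 0.0
    d = sparse.diags(keep)

    def cut(m):
        out = d.dot(m).dot(d).tocsr()
        out.eliminate_zeros()
        return out

    return ConnectivityMatrices(
        W_EE_local=cut(conn.W_EE_local),
        W_EI_local=cut(conn.W_EI_local),
        W_EE_remote=cut(conn.W_EE_remote),
        geometry=conn.geometry,
        provenance={**conn.provenance,
                    "resection": {"shape": mask.shape,
                                  "n_removed": int(len(mask.indices))}},
    )


def place_microdomains(geometry: SheetGeometry, n_patches: int,
                       percent_hyperactive: float, seed: int = 0,
                       boundary_margin: int = 3, separation: int = 2,
                       max_tries: int = 200):
    """Random disjoint contiguous patches covering the requested percentage.

    Each patch is grown by randomized breadth-first accretion from a random
    seed column (approximately round blobs), rejection-sampled so patches
    keep a ``separation``-column gap from each other and stay
    ``boundary_margin`` columns away from the sheet edge.  Returns a list of
    ``n_patches`` index arrays whose union has exactly
    ``round(percent/100 * n_columns)`` columns.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if not (0 < percent_hyperactive <= 100):
        raise ValueError("percent_hyperactive must be in (0, 100]")
    total = int(round(percent_hyperactive / 100.0 * geometry.n_columns))
    if total < n_patches:
        raise ValueError("fewer hyperactive columns than patches")
    sizes = np.full(n_patches, total // n_patches)
    sizes[: total % n_patches] += 1

    rng = np.random.default_rng(np.random.Philox(key=seed))
    nr, nc = geometry.n_rows, geometry.n_cols

    for attempt in range(max_tries):
        blocked = np.zeros((nr, nc), dtype=bool)
        blocked[:boundary_margin, :] = True
        blocked[nr - boundary_margin:, :] = True
        blocked[:, :boundary_margin] = True
        blocked[:, nc - boundary_margin:] = True
        patches = []
        ok = True
        for size in sizes:
            patch = _grow_patch(rng, blocked, nr, nc, int(size))
            if patch is None:
                ok = False
                break
            patches.append(patch)
            # block the patch plus the separation margin
            pr, pc = patch[:, 0], patch[:, 1]
            for dr in range(-separation, separation + 1):
                for dc in range(-separation, separation + 1):
                    rr = np.clip(pr + dr, 0, nr - 1)
                    cc = np.clip(pc + dc, 0, nc - 1)
                    blocked[rr, cc] = True
        if ok:
            return [np.sort(p[:, 0] * nc + p[:, 1]) for p in patches]
    raise RuntimeError(
        f"could not place {n_patches} disjoint patches of total size {total} "
        f"on a {nr}x{nc} sheet after {max_tries} attempts; reduce the "
        "percentage, patch count or margins")


def _grow_patch(rng, blocked, nr, nc, size):
    """Randomized BFS accretion; returns (size, 2) row/col array or None."""
    free = np.argwhere(~blocked)
    if len(free) == 0:
        return None
    for _ in range(20):
        seed_rc = free[rng.integers(len(free))]
        cells = {tuple(seed_rc)}
        frontier = set()
        _push_neighbors(tuple(seed_rc), cells, frontier, blocked, nr, nc)
        while len(cells) < size and frontier:
            nxt = list(frontier)
            pick = nxt[rng.integers(len(nxt))]
            frontier.discard(pick)
            cells.add(pick)
            _push_neighbors(pick, cells, frontier, blocked, nr, nc)
        if len(cells) == size:
            return np.array(sorted(cells))
    return None


def _push_neighbors(rc, cells, frontier, blocked, nr, nc):
    r, c = rc
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < nr and 0 <= cc < nc and not blocked[rr, cc] \
                and (rr, cc) not in cells:
            frontier.add((rr, cc))


def save_connectivity(conn: ConnectivityMatrices, prefix: str) -> None:
    """Persist the three operators as Matrix Market files plus a JSON
    provenance sidecar (``<prefix>_{EE_local,EI_local,EE_remote}.mtx`` and
    ``<prefix>_provenance.json``)."""
    import json
    from scipy.io import mmwrite

    for name, m in zip(("EE_local", "EI_local", "EE_remote"),
                       conn.matrices()):
        mmwrite(f"{prefix}_{name}.mtx", m)
    side = {"geometry": {"n_rows": conn.geometry.n_rows,
                         "n_cols": conn.geometry.n_cols,
                         "macro_size": conn.geometry.macro_size},
            "provenance": conn.provenance}
    with open(f"{prefix}_provenance.json", "w") as f:
        json.dump(side, f, indent=2)


def load_connectivity(prefix: str) -> ConnectivityMatrices:
    import json
    from scipy.io import mmread

    with open(f"{prefix}_provenance.json") as f:
        side = json.load(f)
    geom = SheetGeometry(n_rows=side["geometry"]["n_rows"],
                         n_cols=side["geometry"]["n_cols"],
                         macro_size=side["geometry"]["macro_size"])
    mats = [mmread(f"{prefix}_{name}.mtx").tocsr()
            for name in ("EE_local", "EI_local", "EE_remote")]
    return ConnectivityMatrices(*mats, geometry=geom,
                                provenance=side["provenance"])
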