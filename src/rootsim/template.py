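"""Synthetic heart-stage root template.

Generates an idealized embryonic root meristem: bilaterally symmetric cell
files (vascular, pericycle, endodermis, cortex, epidermis from the center
outward) converging on a stem-cell niche with exactly two quiescent-center
(QC) cells, flanked by cortex/endodermis initials (CEI) and epidermis/LRC
initials, with columella initials and columella below the QC and a lateral
root cap (LRC) sheathing a tapered tip.  The topmost vascular cells are
flagged as the shoot-derived auxin Source and the topmost outer epidermal
cells as auxin Sinks.

The generator is purely deterministic: cell positions follow a rectangular
column grid whose tip rows are radially scaled to taper.  Cells spanning
several columns keep the intermediate grid vertices in their rings, so every
wall segment is shared by at most two cells by construction.  All anisotropy
vectors start at zero length (non-polar initial condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .cell_complex import CellComplex
from .errors import ConfigurationError

__all__ = ["TemplateConfig", "build_synthetic_root_template", "expected_cell_count"]

#: file types from the organ surface inward
_OUTER_TYPES = ["Epidermis", "Cortex", "Endodermis", "Pericycle"]


@dataclass
class TemplateConfig:
    n_files: int = 5            # cell files per half (vascular..epidermis)
    cells_per_file: int = 6     # body rows above the niche
    cell_width: float = 8.0     # um
    cell_height: float = 8.0    # um
    columella_rows: int = 2
    a_max_factor: float = 1.5   # division threshold relative to template area
    rsi_rows: int = 2           # top body rows labelled root-shoot interface
    #: radial scale of successive tip row boundaries (from the niche down)
    taper: Sequence[float] = field(
        default_factory=lambda: (1.0, 0.95, 0.85, 0.72, 0.6, 0.45, 0.3))


def _file_type(c: int, n: int) -> str:
    """Tissue type of body column ``c`` (1 = innermost) of ``n`` files."""
    from_outside = n - c
    if from_outside < len(_OUTER_TYPES):
        return _OUTER_TYPES[from_outside]
    return "Vascular"


def _tip_rows(n: int, columella_rows: int) -> List[List[Tuple[int, int, str]]]:
    """Tip row layouts as (c_start, c_end, type) spans per half, top to bottom."""
    n_vasc = max(n - 4, 1)
    niche_w = min(max(n - 3, 1), n)         # columns spanned by QC/columella
    rows: List[List[Tuple[int, int, str]]] = []
    # initials row: vascular initials, pericycle, CEI (endodermis+cortex), epid/LRC
    initials: List[Tuple[int, int, str]] = [(c, c, "VascularInitial")
                                            for c in range(1, n_vasc + 1)]
    if n >= 4:
        initials.append((n - 3, n - 3, "Pericycle"))
    if n >= 3:
        initials.append((max(n - 2, 1), n - 1, "CEI"))
    initials.append((n, n, "EpidermisLRCInitial"))
    rows.append(initials)
    # QC row
    qc_row: List[Tuple[int, int, str]] = [(1, niche_w, "QC")]
    if n - 1 >= niche_w + 1:
        qc_row.append((niche_w + 1, n - 1, "CEID"))
    qc_row.append((n, n, "LRC"))
    rows.append(qc_row)
    # columella initials
    ci_row: List[Tuple[int, int, str]] = [(1, niche_w, "ColumellaInitial")]
    if n >= niche_w + 1:
        ci_row.append((niche_w + 1, n, "LRC"))
    rows.append(ci_row)
    # columella proper
    for _ in range(columella_rows):
        col_row: List[Tuple[int, int, str]] = [(1, niche_w, "Columella")]
        if n >= niche_w + 1:
            col_row.append((niche_w + 1, n, "LRC"))
        rows.append(col_row)
    # LRC cap sheathing the tip
    rows.append([(1, max(n - 2, 1), "LRC")])
    return rows


def expected_cell_count(config: TemplateConfig) -> int:
    """Closed-form cell count of the generated layout."""
    n = config.n_files
    body = 2 * n * config.cells_per_file
    tip = sum(2 * len(row) for row in _tip_rows(n, config.columella_rows))
    return body + tip


def build_synthetic_root_template(config: TemplateConfig | None = None) -> CellComplex:
    """Build the embryonic set-point mesh described above."""
    cfg = config or TemplateConfig()
    n = cfg.n_files
    if n < 1:
        raise ConfigurationError("n_files must be >= 1")
    if n < 5:
        raise ConfigurationError(
            "the niche layout needs the five tissue files; n_files must be >= 5")
    if cfg.cells_per_file < 1:
        raise ConfigurationError("cells_per_file must be >= 1")
    w, h = cfg.cell_width, cfg.cell_height
    tip_rows = _tip_rows(n, cfg.columella_rows)
    n_tip = len(tip_rows)
    taper = list(cfg.taper)
    if len(taper) < n_tip + 1:
        raise ConfigurationError(
            f"taper needs at least {n_tip + 1} entries, got {len(taper)}")

    cx = CellComplex()
    # row boundary index r: 0 (top) .. cells_per_file (niche top, y=0) .. +n_tip
    y_top = cfg.cells_per_file * h
    vcache: Dict[Tuple[int, int], int] = {}

    def boundary_y(r: int) -> float:
        return y_top - r * h

    def boundary_scale(r: int) -> float:
        if r <= cfg.cells_per_file:
            return 1.0
        return taper[r - cfg.cells_per_file]

    def vid(r: int, j: int) -> int:
        key = (r, j)
        if key not in vcache:
            x = boundary_scale(r) * (j - n) * w
            vcache[key] = cx.add_vertex(x, boundary_y(r))
        return vcache[key]

    def add_quad(r_top: int, j_a: int, j_b: int, cell_type: str, region: str) -> None:
        r_bot = r_top + 1
        ring = [vid(r_bot, j) for j in range(j_a, j_b + 1)]
        ring += [vid(r_top, j) for j in range(j_b, j_a - 1, -1)]
        cx.new_cell(cell_type, ring, region=region)

    # body files
    for r in range(cfg.cells_per_file):
        region = "RSI" if r < cfg.rsi_rows else "BPE"
        for side in (-1, 1):
            for c in range(1, n + 1):
                ctype = _file_type(c, n)
                if r == 0:
                    # the entire top row is the shoot boundary: auxin enters
                    # through the central stele files (vasculature and
                    # pericycle) and is evacuated through the rest,
                    # outermost epidermal cells included
                    ctype = "Source" if ctype in ("Vascular", "Pericycle") \
                        else "Sink"
                j_lo = n + (c - 1) if side > 0 else n - c
                add_quad(r, j_lo, j_lo + 1, ctype, region)
    # tip rows
    for k, row in enumerate(tip_rows):
        r_top = cfg.cells_per_file + k
        for side in (-1, 1):
            for c1, c2, ctype in row:
                if side > 0:
                    j_a, j_b = n + c1 - 1, n + c2
                else:
                    j_a, j_b = n - c2, n - c1 + 1
                add_quad(r_top, j_a, j_b, ctype, "BPE")

    cx.rebuild_walls(preserve=False)
    cx.add_centers()
    for cell in cx.cells.values():
        area = cx.cell_area(cell.id)
        cell.a_max = cfg.a_max_factor * area
        cell.a_min = 0.5 * area
        cell.af = np.zeros(2)
    cx.validate()
    return cx


def attachment_vertices(cx: CellComplex,
                        center_half_width: float = 8.0) -> Tuple[List[int], List[int]]:
    """Static attachment of the organ to the shoot: the topmost cell row.

    Returns ``(fully_pinned, y_pinned)``: the central column of the top row
    is pinned in both axes (anchoring the organ), the rest of the row is
    pinned vertically only, so the attachment cannot stretch rootward but
    may widen with the tissue.
    """
    y_max = float(np.max(cx.vertices[:, 1]))
    row = set()
    for cell in cx.cells.values():
        if any(cx.vertices[v, 1] > y_max - 1e-9 for v in cell.ring):
            row.update(cell.ring)
            if cell.center >= 0:
                row.add(cell.center)
    full = [v for v in row if abs(cx.vertices[v, 0]) <= center_half_width]
    y_only = [v for v in row if v not in set(full)]
    return sorted(full), sorted(y_only)


def pinned_vertices(cx: CellComplex) -> List[int]:
    """All attachment vertices (see :func:`attachment_vertices`)."""
    full, y_only = attachment_vertices(cx)
    return sorted(set(full) | set(y_only))
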