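"""Figure export: one JPEG per figure or a single multi-page PDF."""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Mapping, Sequence

__all__ = ["print_graphs"]


def _slug(key) -> str:
    text = "_".join(map(str, key)) if isinstance(key, tuple) else str(key)
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", text) or "figure"


def print_graphs(
    figures: Mapping[object, object] | Sequence[object],
    format: str = "jpeg",
    destination: str | Path = ".",
    *,
    basename: str = "figure",
) -> list[Path]:
    """Export a collection of matplotlib figures.

    ``format="jpeg"`` writes one file per figure, named deterministically
    from the collection keys (or position); ``format="pdf"`` writes a single
    multi-page document.  The destination is checked for writability before
    any file is produced.
    """
    if isinstance(figures, Mapping):
        items = [( _slug(k), f) for k, f in figures.items()]
    else:
        items = [(f"{basename}_{i:03d}", f) for i, f in enumerate(figures)]
    if not items:
        raise ValueError("empty figure collection")
    if format not in {"jpeg", "pdf"}:
        raise ValueError(f"format must be 'jpeg' or 'pdf', got {format!r}")
    dest = Path(destination)
    if not dest.is_dir():
        raise OSError(f"destination {dest} is not an existing directory")
    if not os.access(dest, os.W_OK):
        raise OSError(f"destination {dest} is not writable")

    written: list[Path] = []
    if format == "jpeg":
        for name, fig in items:
            path = dest / f"{name}.jpeg"
            fig.savefig(path, dpi=150)
            written.append(path)
    else:
        from matplotlib.backends.backend_pdf import PdfPages

        path = dest / f"{basename}.pdf"
        with PdfPages(path) as pdf:
            for _name, fig in items:
                pdf.savefig(fig)
        written.append(path)
    return written
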