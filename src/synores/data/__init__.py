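"""Packaged gene-set fixtures.

The subset marker sets and the B-cell module shipped here are SYNTHETIC
placeholders (synthetic gene names, one file per library): the published
cell-subset marker lists and the 71-gene B-cell module are defined in
external resources and are not redistributed. To use the published lists,
export them to GMT and pass the path to the scoring functions instead.
"""
from importlib import resources

from ..io import read_gmt


def load_placeholder_subset_markers() -> dict[str, list[str]]:
    """Synthetic stand-in for the cell-subset marker sets (SC-F1..SC-B4)."""
    with resources.as_file(
        resources.files(__package__) / "synthetic_subset_markers.gmt"
    ) as path:
        return read_gmt(path)


def load_placeholder_bcell_module() -> list[str]:
    """Synthetic stand-in for the 71-gene B-cell module."""
    with resources.as_file(
        resources.files(__package__) / "synthetic_bcell_module.gmt"
    ) as path:
        return next(iter(read_gmt(path).values()))
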