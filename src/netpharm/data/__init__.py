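"""Packaged fixtures transcribed from the study's printed tables.

``table1_compounds.csv``: the 13 ingredients/metabolites with identity and
content metadata. ``table2_docking.csv``: the 38 accepted docking results in
the printed-table dialect (compound named once per block). ``fig4_crosstalk.csv``:
the curated directed cross-talk map between the seven signalling pathways.
"""

from importlib import resources
from pathlib import Path

__all__ = ["table1_compounds_path", "table2_docking_path", "fig4_crosstalk_path"]


def _path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def table1_compounds_path() -> Path:
    return _path("table1_compounds.csv")


def table2_docking_path() -> Path:
    return _path("table2_docking.csv")


def fig4_crosstalk_path() -> Path:
    return _path("fig4_crosstalk.csv")
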