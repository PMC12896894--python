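"""Small reference datasets bundled with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_io import read_table

__all__ = ["load_reference_properties"]

_SCHEMA = {
    "gene_name": str, "gene_id": str, "length": int, "mw_kda": float,
    "pi": float, "aliphatic_index": float, "instability_index": float,
    "gravy": float,
}


def load_reference_properties() -> pd.DataFrame:
    """Published physicochemical properties of the 28 kiwifruit XYLPs.

    One row per family member: length (residues), molecular weight (kDa),
    theoretical pI, aliphatic index, instability index, GRAVY, plus the
    external-predictor annotations (subcellular localization, GPI anchor).
    Used as the worked-example fixture for the characterization summaries.
    """
    with resources.as_file(
        resources.files("xylpscan") / "data" / "acxylp_properties.tsv"
    ) as p:
        return read_table(p, _SCHEMA)
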