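"""Small shared helpers."""

from __future__ import annotations


def normalize_species_name(name: str) -> str:
    """Canonical form for species identifiers: spaces -> underscores, case-folded.

    Used everywhere species names from datasets are matched against tree tip
    labels, so that e.g. ``"Dermochelys coriacea"`` and ``"dermochelys_coriacea"``
    refer to the same taxon.
    """
    return "_".join(str(name).strip().split()).casefold()
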