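"""shikispec: shikimic-acid chemometrics from canopy hyperspectral imaging
and chlorophyll fluorescence.

Submodules
----------
synth    synthetic glyphosate-trial generator (spectra, ChlF tables, cubes)
hsio     hyperspectral I/O, calibration, segmentation, preprocessing
featsel  SPA / random-frog / backward-refinement variable selection
chemo    PLSR, PLS-DA, SPXY splitting, LV selection, metrics
chemimg  pixel-wise prediction maps
pipeline end-to-end orchestrated study with a reproducible report
"""

from importlib.resources import files as _files

from . import chemimg, chemo, featsel, hsio, pipeline, synth  # noqa: F401

__version__ = "0.1.0"


def printed_equation_model():
    """The fixed 11-wavelength PLSR calibration model (printed coefficients).

    Loaded from packaged JSON; see its metadata for the 534 nm band-label
    note.
    """
    from .chemo import model_from_json
    import json

    text = (_files("shikispec") / "data" / "printed_equation_model.json").read_text()
    return model_from_json(json.loads(text))
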