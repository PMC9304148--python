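"""carhscan: operator discovery and binding biophysics for B12-dependent
photoregulation of bacterial carotenogenesis.

The package covers the computational side of characterising
CarH/CarA-type photoreceptor/repressors:

* classifying protein sequences as CarH (B12-dependent photoreceptor)
  or CarA (B12-independent paralogue) homologues from degenerate motif
  co-occurrence (:mod:`carhscan.homologs`);
* discovering candidate operators as runs of tandem 11-bp direct
  repeats in promoter windows (:mod:`carhscan.operators`);
* modelling cooperative dimer binding to repeat arrays — EMSA band
  categories, footprint geometry, Hill fits of titrations, SEC-based
  oligomer calls and qRT-PCR normalisation (:mod:`carhscan.binding`);
* seeded synthetic-data generators for all of the above
  (:mod:`carhscan.simulate`).
"""

from importlib import resources
import json

__version__ = "0.1.0"


def load_carh_cfu_fixture() -> dict:
    """Ground-truth CarH_Cfu EMSA/SEC parameters packaged with carhscan."""
    with resources.files("carhscan.data").joinpath("carh_cfu_emsa.json").open() as fh:
        return json.load(fh)
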