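"""Packaged example data.

All packaged files are synthetic and labelled as such in their filenames:

* ``b2_panel_synthetic.tsv`` — a 43-strain B2 panel (20 human-exclusive,
  10 human non-exclusive, 13 animal) whose per-gene marginal prevalences
  are reconstructed exactly from the published per-group percentages.
  The per-strain joint gene pattern and the subgroup labels are a
  synthetic convention, not observed data (marginal-preserving stand-in
  for the unavailable supplementary strain table).
* ``example_qpcr_synthetic.tsv`` / ``example_hosts_synthetic.tsv`` — a
  15-sample cohort generated by :func:`colitype.simulate.simulate_cohort`
  with the default templates, seed 7, 3 samples per enterocolitype.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import io
from .hosts import HostProfile
from .quantify import QPCRCounts
from .virulence import StrainVFProfile


def _data_path(name: str) -> Path:
    return Path(resources.files("colitype").joinpath("data", name))


def b2_panel_path() -> Path:
    """Path to the packaged synthetic 43-strain B2 panel."""
    return _data_path("b2_panel_synthetic.tsv")


def load_b2_panel() -> list[StrainVFProfile]:
    return io.read_strain_table(b2_panel_path())


def example_cohort_paths() -> tuple[Path, Path]:
    """(qPCR table, host metadata) paths of the packaged example cohort."""
    return (
        _data_path("example_qpcr_synthetic.tsv"),
        _data_path("example_hosts_synthetic.tsv"),
    )


def load_example_cohort() -> tuple[list[QPCRCounts], list[HostProfile]]:
    qpcr_path, hosts_path = example_cohort_paths()
    return io.read_qpcr_table(qpcr_path), io.read_metadata(hosts_path)
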