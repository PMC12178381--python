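"""Shared fixtures: one synthetic study bundle per session, fully analyzed.

The bundle is generated by :mod:`panelaudit.synth` with a fixed seed; its
manifest holds ground truth computed by per-base set arithmetic,
independent of the interval algebra under test.
"""

import json
import os

import pytest

import panelaudit as pa
from panelaudit.synth import make_bundle

SEED = 1


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_bundle")
    return make_bundle(str(outdir), seed=SEED)


@pytest.fixture(scope="session")
def manifest(bundle):
    with open(bundle.manifest_path) as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def annotation(bundle):
    return pa.read_annotation(bundle.genome.gtf_path, "gtf")


@pytest.fixture(scope="session")
def alpha_panel(bundle):
    f = bundle.panels["ALPHA"]
    return pa.load_panel("ALPHA", f.target_bed, f.mask_bed)


@pytest.fixture(scope="session")
def beta_panel(bundle):
    f = bundle.panels["BETA"]
    return pa.load_panel("BETA", f.target_bed)


@pytest.fixture(scope="session")
def variant_tables(bundle):
    clinvar, _ = pa.read_clinvar(os.path.join(bundle.outdir, "clinvar.tsv"))
    cosmic, _ = pa.read_cmc(os.path.join(bundle.outdir, "cmc.tsv"))
    return clinvar, cosmic


@pytest.fixture(scope="session")
def alpha_analysis(alpha_panel, annotation, variant_tables):
    clinvar, cosmic = variant_tables
    return pa.analyze_panel(alpha_panel, annotation, clinvar, cosmic)


@pytest.fixture(scope="session")
def beta_analysis(beta_panel, annotation, variant_tables):
    clinvar, cosmic = variant_tables
    return pa.analyze_panel(beta_panel, annotation, clinvar, cosmic)


@pytest.fixture(scope="session")
def workspace(alpha_analysis, beta_analysis):
    return pa.PanelWorkspace([alpha_analysis, beta_analysis])


def base_set(intervals):
    """Brute-force per-base oracle: the set of (chrom, pos) covered."""
    out = set()
    for iv in intervals:
        for p in range(iv.start, iv.end + 1):
            out.add((iv.chrom, p))
    return out
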