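import numpy as np
import pytest

from proglu.chem import default_registry
from proglu.digest import PeptideForm, ProteinRecord
from proglu.synthetic import demo_protein


@pytest.fixture(scope="session")
def registry():
    return default_registry()

@pytest.fixture(scope="session")
def cam(registry):
    return registry["Carbamidomethyl"]

@pytest.fixture(scope="session")
def pro_glu(registry):
    return registry["Pro>Glu"]

@pytest.fixture(scope="session")
def prx6_like():
    """Synthetic demo protein with DFTPVCTTELGR at residues 42-53."""
    return demo_protein()

@pytest.fixture
def prx6_peptide(cam):
    """The signature peptide, carbamidomethylated, at its demo coordinates."""
    return PeptideForm(
        sequence="DFTPVCTTELGR", protein="PRX6_SYN", start=42, end=53,
        mods=((6, cam),),
    )

@pytest.fixture
def prx6_converted(prx6_peptide, pro_glu):
    return prx6_peptide.with_mods(prx6_peptide.mods + ((4, pro_glu),))


def make_ms2(form, charge=2, rt=30.0, jitter=0.0, dropout=0.0, noise=0,
             rng=None, scan_id="scan=2", source="scan=1"):
    """Deterministic (or seeded) MS2 scan from a peptide form's b/y ladder."""
    from proglu.search import theoretical_fragments
    from proglu.spectra_io import Ms2Scan

    rng = rng or np.random.default_rng(0)
    mzs, intens = [], []
    for _label, theo in theoretical_fragments(form):
        if dropout and rng.random() < dropout:
            continue
        mzs.append(theo + (rng.normal(0.0, jitter) if jitter else 0.0))
        intens.append(1000.0 * (1 + rng.random()))
    if noise:
        mzs.extend(rng.uniform(150.0, 1500.0, size=noise))
        intens.extend(rng.uniform(10.0, 100.0, size=noise))
    order = np.argsort(mzs)
    mz_arr = np.array(mzs)[order]
    int_arr = np.array(intens)[order]
    keep = np.concatenate([[True], np.diff(mz_arr) > 1e-9])
    return Ms2Scan(scan_id, rt, form.mz(charge), charge, source,
                   mz_arr[keep], int_arr[keep])
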