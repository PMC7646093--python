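import random

import pytest

from dialibkit.chem import ModifiedPeptide, Peak, PrecursorKey, Spectrum, annotate_fragments
from dialibkit.consensus import ReplicateGroup
from dialibkit.psm import PSMRecord, PSMTable


def make_record(
    seq="ESDTSYVSLK",
    charge=2,
    rt=600.0,
    scan="scan_1",
    proteins=("sp|P02741|CRP_HUMAN",),
    score=50.0,
    intensity=1e6,
    run="run0",
    **kw,
):
    return PSMRecord(
        scan_id=scan,
        rt_seconds=rt,
        peptide=ModifiedPeptide(seq),
        charge=charge,
        proteins=proteins,
        score=score,
        precursor_intensity=intensity,
        run_id=run,
        **kw,
    )


def fragment_spectrum(seq="ESDTSYVSLK", charge=2, rt=600.0, scan="scan_1", n_frag=8, jitter=0.0, extra_peaks=()):
    """Spectrum holding the first n_frag singly-charged y ions plus extras."""
    pep = ModifiedPeptide(seq)
    ions = [i for i in annotate_fragments(pep, 1) if i.series == "y"][:n_frag]
    rng = random.Random(hash(scan) & 0xFFFF)
    peaks = [Peak(i.mz + jitter * rng.uniform(-1, 1), 1000.0 / (k + 1)) for k, i in enumerate(ions)]
    peaks += [Peak(mz, inten) for mz, inten in extra_peaks]
    return Spectrum(peaks=peaks, precursor=PrecursorKey(pep, charge), rt_seconds=rt, scan_id=scan)


@pytest.fixture
def replicate_group():
    members = []
    for k in range(3):
        rec = make_record(scan=f"scan_{k}", rt=600.0 + k, score=40.0 + k, run=f"run{k}")
        members.append((rec, fragment_spectrum(scan=f"scan_{k}", rt=600.0 + k)))
    return ReplicateGroup(PrecursorKey(ModifiedPeptide("ESDTSYVSLK"), 2), members)


@pytest.fixture
def small_table():
    recs = [
        make_record(seq="ESDTSYVSLK", scan="s1", rt=100.0),
        make_record(seq="SGDFGPEVTR", scan="s2", rt=900.0, proteins=("sp|P10001|A_HUMAN",)),
        make_record(seq="LATQSNEITIPVTFESR", scan="s3", rt=1700.0, proteins=("sp|P10002|B_HUMAN",)),
    ]
    return PSMTable(recs, {"run0": 3600.0})
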