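import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from meshrank.linktable import build_link_table
from meshrank.medline import PublicationRecord
from meshrank.vocabulary import MeshDescriptor

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_vocabulary():
    return [
        MeshDescriptor("Neoplasms", "D009369", ("C04",)),
        MeshDescriptor("Lung Neoplasms", "D008175", ("C04.588.894",)),
        MeshDescriptor("Humans", "D006801", ("B01.050.150",)),
        MeshDescriptor("Disease", "D004194", ("C23.550.288",)),
    ]


@pytest.fixture
def toy_records():
    return [
        PublicationRecord(pmid=1, date=dt.date(1995, 3, 1), mesh_headings=("Neoplasms",)),
        PublicationRecord(pmid=2, date=dt.date(1996, 7, 2), mesh_headings=("Humans",)),
        PublicationRecord(
            pmid=3,
            date=dt.date(1997, 1, 3),
            mesh_headings=("Neoplasms", "Lung Neoplasms"),
        ),
    ]


@pytest.fixture
def toy_table(toy_records, toy_vocabulary):
    return build_link_table(toy_records, toy_vocabulary)
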