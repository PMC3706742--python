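"""Shared fixtures: the published GO stanza/GAF examples and synthetic sets."""

import pytest

from gotextcat import SynthConfig, generate

# A GO descriptor as distributed in the ontology flat file (the
# "regulation of secondary shoot formation" term), including the printed
# variant of the id tag and quote style.
TABLE1_STANZA = """\
[Term]
GO_id: GO:2000032
name: regulation of secondary shoot formation
namespace: biological_process
def: 'Any process that modulates the frequency, rate or extent of secondary shoot formation.'
synonym: 'regulation of auxiliary shoot formation' [EXACT]
synonym: 'regulation of auxillary shoot formation' [EXACT]
is_a: GO:0022603 ! regulation of anatomical structure morphogenesis
is_a: GO:0048831 ! regulation of shoot development
"""

# The same annotation as a GAF 2.x row: UniProtKB gene product TCP12
# (A0AQW4) annotated with GO:2000032 from PMID 17307924, evidence IMP,
# annotation date 23 August 2010.
TABLE3_GAF_ROW = (
    "UniProtKB\tA0AQW4\tTCP12\t\tGO:2000032\tPMID:17307924\tIMP\t\tP\t"
    "Transcription factor TCP12\t\tprotein\ttaxon:3702\t2010/08/23\tTAIR\t\t\n"
)


@pytest.fixture(scope="session")
def recovery_set():
    """Default parameter-recovery world: 50 terms x 40 docs, fraction 0.6."""
    return generate(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def small_set():
    """A small synthetic world for structural and CLI tests."""
    return generate(
        SynthConfig(
            seed=5,
            n_terms=8,
            docs_per_term=6,
            signature_vocab_size=6,
            background_vocab_size=80,
            doc_length=40,
            year_range=(2008, 2011),
        )
    )
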