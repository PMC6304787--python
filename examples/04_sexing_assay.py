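"""PCR sexing of simulated samples with an amplification control.

The locus is hemizygous on the male homologue, so locus amplicons
(833/309 nt) appear only in males; an 18S-rDNA-analog control product
(757 nt) gates template integrity. A sample without the control is
called indeterminate regardless of the locus assays.
"""

from nixlocus.pcr import sex_call
from nixlocus.synthetic import (
    GENOMIC_DNA,
    Sample,
    fixture_primer_panel,
    make_canonical_fixture,
    make_sample_templates,
)

fixture = make_canonical_fixture(rng_seed=0)
panel = fixture_primer_panel(fixture)

samples = [
    Sample("male_pupa", "male", GENOMIC_DNA, stage="pupa"),
    Sample("female_pupa", "female", GENOMIC_DNA, stage="pupa"),
    Sample("failed_extraction", "male", GENOMIC_DNA, control_present=False),
]
for sample in samples:
    pool = make_sample_templates(fixture, sample, rng_seed=0)
    call = sex_call(sample.sample_id, pool, panel)
    flags = ", ".join(f"{k}={'+' if v else '-'}" for k, v in call.evidence.items())
    print(f"{sample.sample_id:>18}: {call.call:13} ({flags})")
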