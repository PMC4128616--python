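"""Predict V4 18S amplicons with the built-in eukaryote primer pair.

Constructs a synthetic 18S-like template carrying one binding site for
each primer of the TAReuk454FWD1 / TAReukREV3 pair with a 383 bp insert
between them, then predicts the amplicon.  The primer-inclusive product —
what a gel sizes — is 20 + 383 + 18 = 421 bp, the size expected for a
Fragilariopsis cylindrus V4 amplicon.
"""

from Bio.Seq import Seq

from tracepure import (BUILTIN_PRIMERS, amplify, expand_degenerate,
                       random_template)

fwd = BUILTIN_PRIMERS["TAReuk454FWD1"]
rev = BUILTIN_PRIMERS["TAReukREV3"]
print("forward %s: %s (%d expansions)"
      % (fwd.name, fwd.sequence, len(expand_degenerate(fwd.sequence))))
print("reverse %s: %s (%d expansions)"
      % (rev.name, rev.sequence, len(expand_degenerate(rev.sequence))))

insert = random_template(383, seed=42)
template = (random_template(120, seed=1)
            + expand_degenerate(fwd.sequence)[0]
            + insert
            + str(Seq(expand_degenerate(rev.sequence)[0]).reverse_complement())
            + random_template(150, seed=2))

for amp in amplify(template, fwd, rev):
    print("amplicon: start=%d end=%d length=%d bp"
          % (amp.start, amp.end, amp.length))
print()
print("The 421 bp product spans both primers, as a gel band would;")
print("its sequence can seed the chromatogram simulator as a template.")
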