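"""The three flag reasons: inconsistent boundaries, novel region,
unassignable content.

Constructs one chain per failure mode and prints the triage outcome for
each, mirroring the reasons a curation pipeline hands to human curators.
"""
from tmtriage import (AlignmentHit, ChainRecord, ResidueInterval,
                      partition_chain)


def show(title, chain, hits):
    r = partition_chain(chain, hits)
    reasons = ",".join(sorted(x.value for x in r.reasons)) or "-"
    tags = ",".join(sorted(t.value for t in r.architecture_tags)) or "-"
    print(f"{title:28s} {r.outcome.value:13s} reasons={reasons} tags={tags}")


# two comparable hits proposing incompatible parses of the same region
show("competing parses",
     ChainRecord("conflict", 200),
     [AlignmentHit("domA", (ResidueInterval(1, 120),), 120, 0.95, 100.0),
      AlignmentHit("domB", (ResidueInterval(80, 200),), 121, 0.95, 95.0)])

# half the chain has no similarity to any reference domain
show("uncovered region",
     ChainRecord("novel", 300),
     [AlignmentHit("domA", (ResidueInterval(1, 150),), 150, 0.95, 90.0)])

# a synthetic construct with no evidence at all
show("synthetic construct",
     ChainRecord("synth", 120, synthetic_flag=True),
     [])

# a 12-residue peptide
show("peptide", ChainRecord("pep", 12), [])

# Each flagged chain carries the reason a curator needs: INCONSISTENT_
# BOUNDARIES (no consistent parse exists), NOVEL_REGION (a >=30-residue
# run without known homology), or UNASSIGNABLE (non-domain content).
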