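"""Phase unphased diploid consensus sequences into _a/_b allele pairs.

Builds a tiny population in which ten individuals are homozygous for one
of two haplotypes and one individual is heterozygous (R and Y codes),
then phases it with the EM haplotype-frequency model.
"""

from hapnet import Alignment, SequenceRecord, phase_alignment
from hapnet.phasing import Genotype, em_phase

records = [
    SequenceRecord(individual=f"hom{i}", sequence="AATTC") for i in range(5)
] + [
    SequenceRecord(individual=f"hom{i + 5}", sequence="AGTTC") for i in range(4)
] + [
    # R = A/G at column 2: the only heterozygote
    SequenceRecord(individual="het1", sequence="ARTTC"),
]

phased = phase_alignment(Alignment(records))
for rec in phased:
    if rec.individual == "het1":
        print(rec.label, rec.sequence)

result = em_phase(
    [Genotype(individual=r.individual, sequence=r.sequence) for r in records]
)
print("estimated haplotype frequencies:")
for hap, freq in sorted(result.frequencies.items()):
    print(f"  {hap}  {freq:.3f}")
print(f"EM iterations: {len(result.log_likelihoods)}, converged: {result.converged}")

# The heterozygote resolves to the two haplotypes already common in the
# population (AATTC/AGTTC); the frequencies are the EM point estimates of
# each haplotype's share of the 2n allele copies.
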