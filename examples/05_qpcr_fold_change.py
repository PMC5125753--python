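"""Relative RNA quantification by the comparative-CT method.

Computes fold changes 2^(-ΔΔCT) from threshold cycles of a gene of
interest and an internal control in two samples.
"""

from mrnatrack import QpcrSample
from mrnatrack import stats as st

# one transgene copy versus endogenous-only control
sample = QpcrSample(CT_gene=21.3, CT_internal=18.9, label="1x transgene")
reference = QpcrSample(CT_gene=22.6, CT_internal=19.1, label="control")

fold = st.ddct_fold_change(sample, reference)
print(f"ΔCT sample:    {sample.delta_ct:.2f} cycles")
print(f"ΔCT reference: {reference.delta_ct:.2f} cycles")
print(f"fold change:   {fold:.2f}")
print()
print("A fold change above 1 means the sample holds more target RNA than")
print("the reference after normalising to the internal control; each CT")
print("cycle corresponds to a factor of two.")
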