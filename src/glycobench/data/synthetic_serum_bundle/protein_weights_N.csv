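accession,weight
P01009,2
P00450,2
P00738,2
P01857,2
P01023,2
P02763,2
P02765,2
P02787,2
P01876,2
P01871,2
P04070,2
P02790,2
P19827,2
P01042,2
P10909,2
P02749,2
P05155,2
P00734,2
P08603,2
P02748,2
P06727,2
P04196,2
P02760,2
P01008,2
P43652,2
P02751,1
P04004,1
P02774,1
P25311,1
P01011,1
P05546,1
P03952,1
P06681,1
P09871,1
P00751,1
P01031,1
P07357,1
P08571,1
P22792,1
P27169,1
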