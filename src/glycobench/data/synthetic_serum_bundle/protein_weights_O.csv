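accession,weight
P01042,3
P02790,3
P01023,3
P02763,3
P04070,3
P08603,3
P01008,3
P02787,2
P01871,2
P10909,2
P05155,2
P00734,2
P01876,2
P02749,2
P19827,2
P02765,1
P04196,1
P02760,1
P06727,1
P43652,1
P25311,1
P01011,1
P03952,1
P09871,1
P05546,1
P06681,1
P07357,1
P22792,1
P27169,1
P00751,1
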