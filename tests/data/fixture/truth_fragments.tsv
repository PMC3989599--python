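read_id	isoform
frag_g0000_ear_i0_00000	spliced
frag_g0000_ear_i0_00001	spliced
frag_g0000_ear_i0_00002	spliced
frag_g0000_ear_i0_00003	spliced
frag_g0000_ear_i0_00004	spliced
frag_g0000_ear_i0_00005	spliced
frag_g0000_ear_i0_00006	spliced
frag_g0000_ear_i0_00007	spliced
frag_g0000_ear_i0_00008	spliced
frag_g0000_ear_i0_00009	spliced
frag_g0000_ear_i0_00010	spliced
frag_g0000_ear_i0_00011	spliced
frag_g0000_ear_i0_00012	spliced
frag_g0000_ear_i0_00013	spliced
frag_g0000_ear_i0_00014	spliced
frag_g0000_ear_i0_00015	spliced
frag_g0000_ear_i0_00016	spliced
frag_g0000_ear_i0_00017	spliced
frag_g0000_ear_i0_00018	spliced
frag_g0000_ear_i0_00019	spliced
frag_g0000_ear_i0_00020	spliced
frag_g0000_ear_i0_00021	spliced
frag_g0000_ear_i0_00022	spliced
frag_g0000_ear_i0_00023	spliced
frag_g0000_ear_i0_00024	spliced
frag_g0000_ear_i1_00000	retained
frag_g0000_ear_i1_00001	retained
frag_g0000_ear_i1_00002	retained
frag_g0000_ear_i1_00003	retained
frag_g0000_ear_i1_00004	retained
frag_g0000_ear_i1_00005	spliced
frag_g0000_ear_i1_00006	retained
frag_g0000_ear_i1_00007	spliced
frag_g0000_ear_i1_00008	spliced
frag_g0000_ear_i1_00009	spliced
frag_g0000_ear_i1_00010	retained
frag_g0000_ear_i1_00011	spliced
frag_g0000_ear_i1_00012	retained
frag_g0000_ear_i1_00013	retained
frag_g0000_ear_i1_00014	retained
frag_g0000_ear_i1_00015	spliced
frag_g0000_ear_i1_00016	spliced
frag_g0000_ear_i1_00017	spliced
frag_g0000_ear_i1_00018	spliced
frag_g0000_ear_i1_00019	spliced
frag_g0000_ear_i1_00020	retained
frag_g0000_ear_i1_00021	spliced
frag_g0000_ear_i1_00022	spliced
frag_g0000_ear_i1_00023	spliced
frag_g0000_ear_i1_00024	spliced
frag_g0001_mat_i0_00000	spliced
frag_g0001_mat_i0_00001	spliced
frag_g0001_mat_i0_00002	spliced
frag_g0001_mat_i0_00003	spliced
frag_g0001_mat_i0_00004	spliced
frag_g0001_mat_i0_00005	spliced
frag_g0001_mat_i0_00006	spliced
frag_g0001_mat_i0_00007	spliced
frag_g0001_mat_i0_00008	spliced
frag_g0001_mat_i0_00009	spliced
frag_g0001_mat_i0_00010	spliced
frag_g0001_mat_i0_00011	spliced
frag_g0001_mat_i0_00012	spliced
frag_g0001_mat_i0_00013	spliced
frag_g0001_mat_i0_00014	spliced
frag_g0001_mat_i0_00015	spliced
frag_g0001_mat_i0_00016	spliced
frag_g0001_mat_i0_00017	spliced
frag_g0001_mat_i0_00018	spliced
frag_g0001_mat_i0_00019	spliced
frag_g0001_mat_i0_00020	spliced
frag_g0001_mat_i0_00021	spliced
frag_g0001_mat_i0_00022	spliced
frag_g0001_mat_i0_00023	spliced
frag_g0001_mat_i0_00024	spliced
frag_g0001_mat_i1_00000	retained
frag_g0001_mat_i1_00001	spliced
frag_g0001_mat_i1_00002	retained
frag_g0001_mat_i1_00003	retained
frag_g0001_mat_i1_00004	spliced
frag_g0001_mat_i1_00005	spliced
frag_g0001_mat_i1_00006	spliced
frag_g0001_mat_i1_00007	spliced
frag_g0001_mat_i1_00008	retained
frag_g0001_mat_i1_00009	retained
frag_g0001_mat_i1_00010	spliced
frag_g0001_mat_i1_00011	spliced
frag_g0001_mat_i1_00012	spliced
frag_g0001_mat_i1_00013	retained
frag_g0001_mat_i1_00014	spliced
frag_g0001_mat_i1_00015	spliced
frag_g0001_mat_i1_00016	spliced
frag_g0001_mat_i1_00017	spliced
frag_g0001_mat_i1_00018	retained
frag_g0001_mat_i1_00019	spliced
frag_g0001_mat_i1_00020	spliced
frag_g0001_mat_i1_00021	retained
frag_g0001_mat_i1_00022	retained
frag_g0001_mat_i1_00023	retained
frag_g0001_mat_i1_00024	retained
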