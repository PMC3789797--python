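cross,year,n_h,n_ms,printed_ratio
P_Ma,2007,117,0,1:0
P_Sp,2007,126,1,1:0
P_Ma,2008,109,0,1:0
P_Sp,2008,66,2,1:0
F1_MaSp,2007,305,0,1:0
F1_SpMa,2007,233,4,1:0
F2_MaSp,2007,1303,14,1:0
F2_SpMa,2007,550,144,13:3
BC1_[SpMa]Ma,2007,71,42,5:3
BC1_[SpMa]Ma,2008,116,58,5:3
BC1_[SpMa]Sp,2007,71,4,1:0
BC1_[MaSp]Ma,2007,254,2,1:0
BC1_[MaSp]Sp,2007,180,0,1:0
BC1_[MaSp]Sp,2008,151,1,1:0
BC2_H,2008,528,503,1:1
BC2_MS,2008,50,199,3:13
BC3_H,2009,289,178,5:3
BC3_MS,2009,44,198,3:13
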