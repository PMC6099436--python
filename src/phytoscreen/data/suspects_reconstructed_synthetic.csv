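name,formula,parent,expected_rt_min
DM-STR,C16H15Cl2N,STR,
OH-STR,C17H17Cl2NO,STR,
OH-DM-STR,C16H15Cl2NO,STR,
di-OH-STR,C17H17Cl2NO2,STR,
STR-ketone,C16H12Cl2O,STR,
DM-STR+Phe,C25H24Cl2N2O,STR,
DM-STR+Tyr,C25H24Cl2N2O2,STR,
OH-DM-STR+Phe,C25H24Cl2N2O2,STR,
DM-CLP,C18H21ClN2,CLP,
didesmethyl-CLP,C17H19ClN2,CLP,
OH-CLP,C19H23ClN2O,CLP,
OH-DM-CLP,C18H21ClN2O,CLP,
CLP-N-oxide,C19H23ClN2O,CLP,
di-OH-CLP,C19H23ClN2O2,CLP,
3-chloroiminodibenzyl,C14H12ClN,CLP,
mCPP,C10H13ClN2,TZN,
OH-mCPP,C10H13ClN2O,TZN,
OH-TZN,C19H22ClN5O2,TZN,
TZN-N-oxide,C19H22ClN5O2,TZN,
di-OH-TZN,C19H22ClN5O3,TZN,
triazolopyridinone,C6H5N3O,TZN,
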