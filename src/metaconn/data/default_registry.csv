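roi_id,structure,subdivision,domain_label,bregma_mm
CPr+1.3_imd,CP,CPr,CPr.imd,+1.3
CPr+1.3_imv,CP,CPr,CPr.imv,+1.3
CPr+1.3_m,CP,CPr,CPr.m,+1.3
CPr+1.3_l,CP,CPr,CPr.l,+1.3
CPr+1.3_vm,CP,CPr,CPr.vm,+1.3
CPr+0.9_imd,CP,CPr,CPr.imd,+0.9
CPr+0.9_imv,CP,CPr,CPr.imv,+0.9
CPr+0.9_m,CP,CPr,CPr.m,+0.9
CPr+0.9_l,CP,CPr,CPr.l,+0.9
CPr+0.9_vm,CP,CPr,CPr.vm,+0.9
CPr+0.9_ic,CP,CPr,CPr.ic,+0.9
CPi+0.5_dm.d,CP,CPi,CPi.dm.d,+0.5
CPi+0.5_dm.im,CP,CPi,CPi.dm.im,+0.5
CPi+0.5_dl.d,CP,CPi,CPi.dl.d,+0.5
CPi+0.5_dl.imd,CP,CPi,CPi.dl.imd,+0.5
CPi+0.5_vm.v,CP,CPi,CPi.vm.v,+0.5
CPi+0.5_vm.vm,CP,CPi,CPi.vm.vm,+0.5
CPi+0.5_vl.v,CP,CPi,CPi.vl.v,+0.5
CPi+0.1_dm.d,CP,CPi,CPi.dm.d,+0.1
CPi+0.1_dm.dm,CP,CPi,CPi.dm.dm,+0.1
CPi+0.1_dm.im,CP,CPi,CPi.dm.im,+0.1
CPi+0.1_dl.d,CP,CPi,CPi.dl.d,+0.1
CPi+0.1_dl.imd,CP,CPi,CPi.dl.imd,+0.1
CPi+0.1_dl.imv,CP,CPi,CPi.dl.imv,+0.1
CPi+0.1_vm.v,CP,CPi,CPi.vm.v,+0.1
CPi+0.1_vm.vm,CP,CPi,CPi.vm.vm,+0.1
CPi+0.1_vl.v,CP,CPi,CPi.vl.v,+0.1
CPi-0.2_dm.d,CP,CPi,CPi.dm.d,-0.2
CPi-0.2_dm.dm,CP,CPi,CPi.dm.dm,-0.2
CPi-0.2_dm.im,CP,CPi,CPi.dm.im,-0.2
CPi-0.2_dm.dl,CP,CPi,CPi.dm.dl,-0.2
CPi-0.2_dl.d,CP,CPi,CPi.dl.d,-0.2
CPi-0.2_dl.imd,CP,CPi,CPi.dl.imd,-0.2
CPi-0.2_vm.v,CP,CPi,CPi.vm.v,-0.2
CPi-0.2_vm.cvm,CP,CPi,CPi.vm.cvm,-0.2
CPi-0.2_vl.imv,CP,CPi,CPi.vl.imv,-0.2
CPi-0.5_dm.d,CP,CPi,CPi.dm.d,-0.5
CPi-0.5_dm.dm,CP,CPi,CPi.dm.dm,-0.5
CPi-0.5_dm.cd,CP,CPi,CPi.dm.cd,-0.5
CPi-0.5_dl.d,CP,CPi,CPi.dl.d,-0.5
CPi-0.5_dl.sc,CP,CPi,CPi.dl.sc,-0.5
CPi-0.5_vm.v,CP,CPi,CPi.vm.v,-0.5
CPi-0.5_vl.v,CP,CPi,CPi.vl.v,-0.5
CPi-0.5_vl.vt,CP,CPi,CPi.vl.vt,-0.5
CPc-0.8_d.dm,CP,CPc,CPc.d.dm,-0.8
CPc-0.8_d.dl,CP,CPc,CPc.d.dl,-0.8
CPc-0.8_d.vm,CP,CPc,CPc.d.vm,-0.8
CPc-0.8_i.d,CP,CPc,CPc.i.d,-0.8
CPc-0.8_i.vm,CP,CPc,CPc.i.vm,-0.8
CPc-0.8_i.vl,CP,CPc,CPc.i.vl,-0.8
CPc-0.8_v.vm,CP,CPc,CPc.v.vm,-0.8
CPc-0.8_v.vl,CP,CPc,CPc.v.vl,-0.8
CPc-1.1_d.dm,CP,CPc,CPc.d.dm,-1.1
CPc-1.1_d.dl,CP,CPc,CPc.d.dl,-1.1
CPc-1.1_i.d,CP,CPc,CPc.i.d,-1.1
CPc-1.1_i.vm,CP,CPc,CPc.i.vm,-1.1
CPc-1.1_i.vl,CP,CPc,CPc.i.vl,-1.1
CPc-1.1_v.vm,CP,CPc,CPc.v.vm,-1.1
CPc-1.1_v.vl,CP,CPc,CPc.v.vl,-1.1
CPc-1.4_d.dm,CP,CPc,CPc.d.dm,-1.4
CPc-1.4_d.dl,CP,CPc,CPc.d.dl,-1.4
CPc-1.4_i.d,CP,CPc,CPc.i.d,-1.4
CPc-1.4_i.vm,CP,CPc,CPc.i.vm,-1.4
CPc-1.4_i.vl,CP,CPc,CPc.i.vl,-1.4
CPc-1.4_v.vm,CP,CPc,CPc.v.vm,-1.4
CPc-1.4_v.vl,CP,CPc,CPc.v.vl,-1.4
SNr-2.9_r.m,SNr,SNr,SNr.r.m,-2.9
SNr-2.9_r.dm,SNr,SNr,SNr.r.dm,-2.9
SNr-2.9_r.l,SNr,SNr,SNr.r.l,-2.9
SNr-2.9_r.dl,SNr,SNr,SNr.r.dl,-2.9
SNr-2.9_r.v,SNr,SNr,SNr.r.v,-2.9
SNr-2.9_r.vl,SNr,SNr,SNr.r.vl,-2.9
SNr-2.9_r.c,SNr,SNr,SNr.r.c,-2.9
SNr-2.9_r.cd,SNr,SNr,SNr.r.cd,-2.9
SNr-3.4_i.m,SNr,SNr,SNr.i.m,-3.4
SNr-3.4_i.dm,SNr,SNr,SNr.i.dm,-3.4
SNr-3.4_i.l,SNr,SNr,SNr.i.l,-3.4
SNr-3.4_i.dl,SNr,SNr,SNr.i.dl,-3.4
SNr-3.4_i.v,SNr,SNr,SNr.i.v,-3.4
SNr-3.4_i.vl,SNr,SNr,SNr.i.vl,-3.4
SNr-3.4_i.c,SNr,SNr,SNr.i.c,-3.4
SNr-3.4_i.cd,SNr,SNr,SNr.i.cd,-3.4
SNr-3.4_i.cv,SNr,SNr,SNr.i.cv,-3.4
SNr-3.9_c.m,SNr,SNr,SNr.c.m,-3.9
SNr-3.9_c.dm,SNr,SNr,SNr.c.dm,-3.9
SNr-3.9_c.l,SNr,SNr,SNr.c.l,-3.9
SNr-3.9_c.dl,SNr,SNr,SNr.c.dl,-3.9
SNr-3.9_c.v,SNr,SNr,SNr.c.v,-3.9
SNr-3.9_c.vl,SNr,SNr,SNr.c.vl,-3.9
SNr-3.9_c.c,SNr,SNr,SNr.c.c,-3.9
SNr-3.9_c.cd,SNr,SNr,SNr.c.cd,-3.9
GPe-0.5_r.dm,GPe,GPe,GPe.r.dm,-0.5
GPe-0.5_r.dl,GPe,GPe,GPe.r.dl,-0.5
GPe-0.5_r.im,GPe,GPe,GPe.r.im,-0.5
GPe-0.5_r.il,GPe,GPe,GPe.r.il,-0.5
GPe-0.5_r.vm,GPe,GPe,GPe.r.vm,-0.5
GPe-0.5_r.vl,GPe,GPe,GPe.r.vl,-0.5
GPe-0.5_r.cd,GPe,GPe,GPe.r.cd,-0.5
GPe-0.5_r.cv,GPe,GPe,GPe.r.cv,-0.5
GPe-0.5_r.c,GPe,GPe,GPe.r.c,-0.5
GPe-0.8_i.dm,GPe,GPe,GPe.i.dm,-0.8
GPe-0.8_i.dl,GPe,GPe,GPe.i.dl,-0.8
GPe-0.8_i.im,GPe,GPe,GPe.i.im,-0.8
GPe-0.8_i.il,GPe,GPe,GPe.i.il,-0.8
GPe-0.8_i.vm,GPe,GPe,GPe.i.vm,-0.8
GPe-0.8_i.vl,GPe,GPe,GPe.i.vl,-0.8
GPe-0.8_i.cd,GPe,GPe,GPe.i.cd,-0.8
GPe-0.8_i.cv,GPe,GPe,GPe.i.cv,-0.8
GPe-0.8_i.c,GPe,GPe,GPe.i.c,-0.8
GPe-0.8_i.x,GPe,GPe,GPe.i.x,-0.8
GPe-1.1_c.dm,GPe,GPe,GPe.c.dm,-1.1
GPe-1.1_c.dl,GPe,GPe,GPe.c.dl,-1.1
GPe-1.1_c.im,GPe,GPe,GPe.c.im,-1.1
GPe-1.1_c.il,GPe,GPe,GPe.c.il,-1.1
GPe-1.1_c.vm,GPe,GPe,GPe.c.vm,-1.1
GPe-1.1_c.vl,GPe,GPe,GPe.c.vl,-1.1
GPe-1.1_c.cd,GPe,GPe,GPe.c.cd,-1.1
GPe-1.1_c.cv,GPe,GPe,GPe.c.cv,-1.1
M2+1.3_m2.m,MOTOR,M2,M2.m2.m,+1.3
M2+1.3_m2.l,MOTOR,M2,M2.m2.l,+1.3
M1+1.3_m1.d,MOTOR,M1,M1.m1.d,+1.3
M1+1.3_m1.v,MOTOR,M1,M1.m1.v,+1.3
M2+0.8_m2.m,MOTOR,M2,M2.m2.m,+0.8
M2+0.8_m2.l,MOTOR,M2,M2.m2.l,+0.8
M1+0.8_m1.d,MOTOR,M1,M1.m1.d,+0.8
M1+0.8_m1.im,MOTOR,M1,M1.m1.im,+0.8
M1+0.8_m1.v,MOTOR,M1,M1.m1.v,+0.8
M2+0.1_m2.m,MOTOR,M2,M2.m2.m,+0.1
M2+0.1_m2.l,MOTOR,M2,M2.m2.l,+0.1
M1+0.1_m1.d,MOTOR,M1,M1.m1.d,+0.1
M1+0.1_m1.im,MOTOR,M1,M1.m1.im,+0.1
M1+0.1_m1.v,MOTOR,M1,M1.m1.v,+0.1
M2-0.5_m2.m,MOTOR,M2,M2.m2.m,-0.5
M1-0.5_m1.d,MOTOR,M1,M1.m1.d,-0.5
M1-0.5_m1.im,MOTOR,M1,M1.m1.im,-0.5
M1-0.5_m1.v,MOTOR,M1,M1.m1.v,-0.5
PrL+1.8_prl.d,PFC,PrL,PrL.prl.d,+1.8
PrL+1.8_prl.v,PFC,PrL,PrL.prl.v,+1.8
IL+1.8_il,PFC,IL,IL.il,+1.8
Cg1+1.8_cg1,PFC,Cg1,Cg1.cg1,+1.8
PrL+1.3_prl.d,PFC,PrL,PrL.prl.d,+1.3
PrL+1.3_prl.v,PFC,PrL,PrL.prl.v,+1.3
IL+1.3_il,PFC,IL,IL.il,+1.3
Cg1+1.3_cg1.d,PFC,Cg1,Cg1.cg1.d,+1.3
Cg1+1.3_cg1.v,PFC,Cg1,Cg1.cg1.v,+1.3
Cg2+1.3_cg2,PFC,Cg2,Cg2.cg2,+1.3
Cg1+0.8_cg1.d,PFC,Cg1,Cg1.cg1.d,+0.8
Cg1+0.8_cg1.v,PFC,Cg1,Cg1.cg1.v,+0.8
Cg2+0.8_cg2.d,PFC,Cg2,Cg2.cg2.d,+0.8
Cg2+0.8_cg2.v,PFC,Cg2,Cg2.cg2.v,+0.8
Cg1+0.1_cg1.d,PFC,Cg1,Cg1.cg1.d,+0.1
Cg1+0.1_cg1.v,PFC,Cg1,Cg1.cg1.v,+0.1
Cg2+0.1_cg2.d,PFC,Cg2,Cg2.cg2.d,+0.1
Cg2+0.1_cg2.v,PFC,Cg2,Cg2.cg2.v,+0.1
Cg2-0.5_cg2,PFC,Cg2,Cg2.cg2,-0.5
AD-0.7_ad,TH,AD,AD.ad,-0.7
AV-0.7_av.d,TH,AV,AV.av.d,-0.7
AV-0.7_av.v,TH,AV,AV.av.v,-0.7
AM-0.7_am,TH,AM,AM.am,-0.7
VA/VL-0.7_va,TH,VA/VL,VA/VL.va,-0.7
AD-1.2_ad,TH,AD,AD.ad,-1.2
AV-1.2_av,TH,AV,AV.av,-1.2
AM-1.2_am,TH,AM,AM.am,-1.2
CM-1.2_cm,TH,CM,CM.cm,-1.2
MD-1.2_md.m,TH,MD,MD.md.m,-1.2
MD-1.2_md.l,TH,MD,MD.md.l,-1.2
VA/VL-1.2_vl.d,TH,VA/VL,VA/VL.vl.d,-1.2
VA/VL-1.2_vl.v,TH,VA/VL,VA/VL.vl.v,-1.2
VM-1.2_vm,TH,VM,VM.vm,-1.2
CM-1.7_cm,TH,CM,CM.cm,-1.7
MD-1.7_md.m,TH,MD,MD.md.m,-1.7
MD-1.7_md.l,TH,MD,MD.md.l,-1.7
MD-1.7_md.c,TH,MD,MD.md.c,-1.7
VA/VL-1.7_vl.d,TH,VA/VL,VA/VL.vl.d,-1.7
VA/VL-1.7_vl.v,TH,VA/VL,VA/VL.vl.v,-1.7
VM-1.7_vm,TH,VM,VM.vm,-1.7
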