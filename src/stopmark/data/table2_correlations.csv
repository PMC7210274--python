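pair,condition,time,r,n,m_r_printed
SSRT - P3 ol,IFG,pre,0.45,18,0.44
SSRT - P3 ol,IFG,peri,0.36,18,0.44
SSRT - P3 ol,IFG,post,0.61,18,0.44
SSRT - P3 ol,VC,pre,0.71,18,0.44
SSRT - P3 ol,VC,peri,0.47,18,0.44
SSRT - P3 ol,VC,post,0.40,18,0.44
SSRT - P3 ol,SHAM,pre,0.60,18,0.44
SSRT - P3 ol,SHAM,peri,-0.29,17,0.44
SSRT - P3 ol,SHAM,post,0.33,18,0.44
SSRT - P3 pl,IFG,pre,0.05,18,0.20
SSRT - P3 pl,IFG,peri,0.25,18,0.20
SSRT - P3 pl,IFG,post,0.16,17,0.20
SSRT - P3 pl,VC,pre,0.36,18,0.20
SSRT - P3 pl,VC,peri,0.20,18,0.20
SSRT - P3 pl,VC,post,0.28,18,0.20
SSRT - P3 pl,SHAM,pre,0.16,18,0.20
SSRT - P3 pl,SHAM,peri,0.22,18,0.20
SSRT - P3 pl,SHAM,post,0.08,18,0.20
SSRT - prEMG,IFG,pre,0.39,18,0.69
SSRT - prEMG,IFG,peri,0.82,17,0.69
SSRT - prEMG,IFG,post,0.57,18,0.69
SSRT - prEMG,VC,pre,0.71,18,0.69
SSRT - prEMG,VC,peri,0.63,17,0.69
SSRT - prEMG,VC,post,0.78,17,0.69
SSRT - prEMG,SHAM,pre,0.67,17,0.69
SSRT - prEMG,SHAM,peri,0.78,18,0.69
SSRT - prEMG,SHAM,post,0.71,18,0.69
prEMG - P3 ol,IFG,pre,0.61,18,0.48
prEMG - P3 ol,IFG,peri,0.42,18,0.48
prEMG - P3 ol,IFG,post,0.56,18,0.48
prEMG - P3 ol,VC,pre,0.75,18,0.48
prEMG - P3 ol,VC,peri,0.44,17,0.48
prEMG - P3 ol,VC,post,0.56,17,0.48
prEMG - P3 ol,SHAM,pre,-0.12,18,0.48
prEMG - P3 ol,SHAM,peri,0.06,17,0.48
prEMG - P3 ol,SHAM,post,0.54,18,0.48
prEMG - P3 pl,IFG,pre,0.55,18,0.21
prEMG - P3 pl,IFG,peri,-0.09,18,0.21
prEMG - P3 pl,IFG,post,0.33,18,0.21
prEMG - P3 pl,VC,pre,0.44,18,0.21
prEMG - P3 pl,VC,peri,-0.08,18,0.21
prEMG - P3 pl,VC,post,0.37,17,0.21
prEMG - P3 pl,SHAM,pre,-0.11,18,0.21
prEMG - P3 pl,SHAM,peri,0.31,18,0.21
prEMG - P3 pl,SHAM,post,0.11,18,0.21
GoRT - P3 ol,IFG,pre,0.08,18,-0.18
GoRT - P3 ol,IFG,peri,-0.10,18,-0.18
GoRT - P3 ol,IFG,post,0.00,18,-0.18
GoRT - P3 ol,VC,pre,-0.06,18,-0.18
GoRT - P3 ol,VC,peri,-0.39,18,-0.18
GoRT - P3 ol,VC,post,-0.28,18,-0.18
GoRT - P3 ol,SHAM,pre,-0.28,18,-0.18
GoRT - P3 ol,SHAM,peri,-0.28,17,-0.18
GoRT - P3 ol,SHAM,post,-0.26,18,-0.18
GoRT - P3 pl,IFG,pre,0.01,18,-0.14
GoRT - P3 pl,IFG,peri,0.25,18,-0.14
GoRT - P3 pl,IFG,post,0.12,18,-0.14
GoRT - P3 pl,VC,pre,-0.17,18,-0.14
GoRT - P3 pl,VC,peri,-0.55,18,-0.14
GoRT - P3 pl,VC,post,-0.23,18,-0.14
GoRT - P3 pl,SHAM,pre,-0.23,18,-0.14
GoRT - P3 pl,SHAM,peri,-0.42,18,-0.14
GoRT - P3 pl,SHAM,post,0.01,18,-0.14
GoRT - prEMG,IFG,pre,-0.32,18,-0.36
GoRT - prEMG,IFG,peri,-0.46,18,-0.36
GoRT - prEMG,IFG,post,-0.47,18,-0.36
GoRT - prEMG,VC,pre,-0.03,18,-0.36
GoRT - prEMG,VC,peri,-0.47,18,-0.36
GoRT - prEMG,VC,post,-0.49,18,-0.36
GoRT - prEMG,SHAM,pre,-0.12,18,-0.36
GoRT - prEMG,SHAM,peri,-0.40,18,-0.36
GoRT - prEMG,SHAM,post,-0.43,18,-0.36
GoRT - SSRT,IFG,pre,-0.38,18,-0.32
GoRT - SSRT,IFG,peri,-0.62,18,-0.32
GoRT - SSRT,IFG,post,-0.30,18,-0.32
GoRT - SSRT,VC,pre,-0.03,18,-0.32
GoRT - SSRT,VC,peri,-0.40,18,-0.32
GoRT - SSRT,VC,post,-0.32,18,-0.32
GoRT - SSRT,SHAM,pre,-0.38,18,-0.32
GoRT - SSRT,SHAM,peri,-0.22,18,-0.32
GoRT - SSRT,SHAM,post,-0.17,18,-0.32
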