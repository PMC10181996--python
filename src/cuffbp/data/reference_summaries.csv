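cohort,feature_set,method,target,mu,sd,ci_low,ci_high,n
healthy,healthy7,lasso,map,-0.18,11.51,-4.88,4.53,23
healthy,healthy7,rf,map,0.27,9.51,-3.62,4.16,23
healthy,healthy7,svm,map,-2.18,9.26,-5.97,1.60,23
healthy,healthy7,ann,map,-0.21,10.15,-4.36,3.94,23
healthy,healthy7,lstm,map,-10.15,10.61,-14.49,-5.82,23
healthy,healthy7,lasso,sbp,1.77,22.46,-7.41,10.95,23
healthy,healthy7,rf,sbp,-0.65,15.28,-6.89,5.59,23
healthy,healthy7,svm,sbp,3.44,13.56,-2.10,8.98,23
healthy,healthy7,ann,sbp,1.27,19.62,-6.75,9.29,23
healthy,healthy7,lstm,sbp,10.63,19.37,2.71,18.55,23
healthy,healthy7,lasso,dbp,-0.62,7.64,-3.74,2.50,23
healthy,healthy7,rf,dbp,-0.08,7.49,-3.14,2.98,23
healthy,healthy7,svm,dbp,1.56,8.62,-1.96,5.08,23
healthy,healthy7,ann,dbp,-0.31,8.76,-3.89,3.27,23
healthy,healthy7,lstm,dbp,9.92,13.51,4.40,15.44,23
compromised,combined,lasso,map,0.03,11.89,-2.05,2.11,126
compromised,combined,rf,map,0.76,8.84,-0.78,2.30,126
compromised,combined,svm,map,0.75,10.56,-1.09,2.59,126
compromised,combined,ann,map,1.17,11.12,-0.77,3.11,126
compromised,combined,lstm,map,2.25,13.39,-0.09,4.59,126
compromised,combined,lasso,sbp,-0.14,18.31,-3.34,3.06,126
compromised,combined,rf,sbp,1.38,15.12,-1.26,4.02,126
compromised,combined,svm,sbp,0.43,17.70,-2.66,3.52,126
compromised,combined,ann,sbp,1.65,21.62,-2.13,5.43,126
compromised,combined,lstm,sbp,3.78,21.82,-0.03,7.59,126
compromised,combined,lasso,dbp,0.03,8.97,-1.53,1.60,126
compromised,combined,rf,dbp,0.45,7.53,-0.86,1.76,126
compromised,combined,svm,dbp,0.91,7.32,-0.37,2.19,126
compromised,combined,ann,dbp,-0.93,9.23,-2.54,0.68,126
compromised,combined,lstm,dbp,1.49,9.17,-0.11,3.09,126
compromised,pat,lasso,map,0.00,12.67,-2.21,2.21,126
compromised,pat,rf,map,-0.08,6.57,-1.23,1.07,126
compromised,pat,svm,map,0.95,9.72,-0.74,2.65,126
compromised,pat,ann,map,-0.26,8.07,-1.67,1.15,126
compromised,pat,lstm,map,2.32,13.46,-0.03,4.67,126
compromised,pat,lasso,sbp,0.00,20.80,-3.63,3.63,126
compromised,pat,rf,sbp,-0.52,15.40,-3.21,2.17,126
compromised,pat,svm,sbp,0.63,16.44,-2.24,3.50,126
compromised,pat,ann,sbp,-1.52,18.12,-4.68,1.64,126
compromised,pat,lstm,sbp,4.13,22.03,0.28,7.98,126
compromised,pat,lasso,dbp,0.00,9.03,-1.58,1.58,126
compromised,pat,rf,dbp,0.14,4.51,-0.65,0.93,126
compromised,pat,svm,dbp,1.09,6.69,-0.08,2.26,126
compromised,pat,ann,dbp,0.37,5.92,-0.66,1.40,126
compromised,pat,lstm,dbp,1.42,9.18,-0.18,3.02,126
compromised,morphology,lasso,map,0.09,12.46,-2.08,2.27,126
compromised,morphology,rf,map,-0.14,8.55,-1.63,1.35,126
compromised,morphology,svm,map,0.89,10.11,-0.87,2.66,126
compromised,morphology,ann,map,-0.94,11.41,-2.93,1.05,126
compromised,morphology,lstm,map,1.36,13.10,-0.93,3.65,126
compromised,morphology,lasso,sbp,-0.11,18.83,-3.39,3.18,126
compromised,morphology,rf,sbp,0.09,17.51,-2.97,3.15,126
compromised,morphology,svm,sbp,0.57,17.24,-2.44,3.58,126
compromised,morphology,ann,sbp,2.49,24.22,-1.74,6.72,126
compromised,morphology,lstm,sbp,4.00,21.99,0.16,7.84,126
compromised,morphology,lasso,dbp,-0.14,8.80,-1.68,1.40,126
compromised,morphology,rf,dbp,0.05,7.61,-1.28,1.38,126
compromised,morphology,svm,dbp,1.01,7.35,-0.27,2.30,126
compromised,morphology,ann,dbp,0.65,11.55,-1.37,2.67,126
compromised,morphology,lstm,dbp,0.045,8.66,-1.47,1.56,126
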